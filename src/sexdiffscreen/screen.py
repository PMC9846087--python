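"""Sex-biased differential-association screening.

For a SNP with sex-stratified effect estimates (beta_f, se_f) and
(beta_m, se_m), the differential statistic is

    dZ = (beta_f - beta_m) / sqrt(se_f**2 + se_m**2)

which is standard normal under the null hypothesis that both sexes share
one true effect, assuming the strata are independent (they contain disjoint
individuals).  Its two-sided p-value is 2 * Phi(-|dZ|).  A candidate panel
is screened with a Bonferroni family-wise bound alpha / m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateStatisticsError
from .gwas_io import PairedSexGwas, SnpPanel


class DeltaZ(NamedTuple):
    """The differential statistic and its two-sided normal p-value.

    Holds scalars or aligned arrays, matching the inputs.
    """

    delta_z: float | np.ndarray
    p_diff: float | np.ndarray


def delta_z(beta_f, se_f, beta_m, se_m) -> DeltaZ:
    """Differential Z statistic between sex strata.

    Antisymmetric in the strata: swapping (beta_f, se_f) with
    (beta_m, se_m) negates delta_z and leaves p_diff unchanged.
    Accepts scalars or broadcastable arrays.
    """
    beta_f, se_f, beta_m, se_m = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (beta_f, se_f, beta_m, se_m))
    )
    pooled = np.hypot(se_f, se_m)
    if np.any(pooled <= 0):
        raise DegenerateStatisticsError(
            "both standard errors are zero; the differential statistic is undefined"
        )
    z = (beta_f - beta_m) / pooled
    p = two_sided_normal_p(z)
    if z.ndim == 0:
        return DeltaZ(float(z), float(p))
    return DeltaZ(z, p)


def two_sided_normal_p(z) -> float | np.ndarray:
    """Two-sided standard-normal tail probability, 2 * Phi(-|z|).

    Monotone decreasing in |z|; equals 1 at z = 0.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise DegenerateStatisticsError(f"non-finite z statistic: {z}")
    p = 2.0 * stats.norm.sf(np.abs(z))
    return float(p) if p.ndim == 0 else p


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise p-value bound alpha / m, returned exactly (unrounded)."""
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1) (got {alpha})")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise ConfigurationError(f"number of tests must be an integer >= 1 (got {m})")
    return alpha / m


@dataclass
class ScreenReport:
    """Outcome of screening a candidate panel for sex-differential effects.

    ``results`` holds one row per tested SNP, sorted ascending by p_diff
    (ties broken by snp_id); ``dropped`` lists panel SNPs absent from the
    harmonized table.  ``threshold`` is always ``alpha / m_tests``.
    """

    alpha: float
    m_tests: int
    threshold: float
    results: pd.DataFrame
    dropped: tuple[str, ...] = field(default_factory=tuple)

    @property
    def significant(self) -> pd.DataFrame:
        return self.results.loc[self.results["significant"]]


def screen_panel(
    paired: PairedSexGwas,
    panel: SnpPanel,
    alpha: float = 0.05,
    m_tests: int | None = None,
) -> ScreenReport:
    """Apply the differential Z test to every panel SNP found in the paired
    table and flag SNPs passing the Bonferroni bound.

    By default the correction denominator is the number of SNPs actually
    tested; pass ``m_tests`` to force the nominal panel size instead (e.g.
    to keep the bound at alpha/172 when some panel SNPs are missing from
    the GWAS).
    """
    found = paired.pairs.loc[paired.pairs["snp_id"].isin(set(panel.snp_ids))]
    dropped = tuple(s for s in panel.snp_ids if s not in set(found["snp_id"]))
    if found.empty:
        raise DegenerateStatisticsError(
            "no panel SNP is present in the paired GWAS table"
        )
    m = int(m_tests) if m_tests is not None else len(found)
    threshold = bonferroni_threshold(alpha, m)

    dz = delta_z(
        found["beta_f"].to_numpy(), found["se_f"].to_numpy(),
        found["beta_m"].to_numpy(), found["se_m"].to_numpy(),
    )
    results = pd.DataFrame(
        {
            "snp_id": found["snp_id"].to_numpy(),
            "beta_f": found["beta_f"].to_numpy(),
            "se_f": found["se_f"].to_numpy(),
            "beta_m": found["beta_m"].to_numpy(),
            "se_m": found["se_m"].to_numpy(),
            "delta_z": np.atleast_1d(dz.delta_z),
            "p_diff": np.atleast_1d(dz.p_diff),
        }
    )
    results["significant"] = results["p_diff"] < threshold
    results = results.sort_values(
        ["p_diff", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)
    return ScreenReport(
        alpha=alpha, m_tests=m, threshold=threshold, results=results, dropped=dropped
    )


def count_suggestive(window, p_max: float = 1e-3):
    """Count records with association p below the suggestive threshold.

    For a single-stratum frame returns an integer; for a
    :class:`PairedSexGwas` returns a ``{"female": n, "male": n}`` dict,
    counting each stratum separately.
    """
    if not 0 < p_max <= 1:
        raise ConfigurationError(f"p_max must be in (0, 1] (got {p_max})")
    if isinstance(window, PairedSexGwas):
        return {
            "female": int((window.pairs["p_f"] < p_max).sum()),
            "male": int((window.pairs["p_m"] < p_max).sum()),
        }
    return int((window["p"].astype(float) < p_max).sum())


def differential_power(delta: float, se_f: float, se_m: float, alpha: float) -> float:
    """Closed-form power of the two-sided differential Z test at level
    ``alpha`` for a true between-sex effect difference ``delta``.

    With noncentrality lam = delta / sqrt(se_f**2 + se_m**2) and critical
    value z = Phi^-1(1 - alpha/2), power is
    1 - Phi(z - lam) + Phi(-z - lam).
    """
    lam = delta / math.hypot(se_f, se_m)
    z = stats.norm.isf(alpha / 2)
    return float(stats.norm.sf(z - lam) + stats.norm.cdf(-z - lam))
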