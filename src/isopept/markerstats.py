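"""Presence-absence marker screening for case/control peptide intensities.

The screen follows a three-step significance procedure on per-peptide
2x2 presence tables (health vs cancer): a Pearson chi-square p-value,
Benjamini-Hochberg adjusted p-values, and Storey-Tibshirani q-values with
pi0 estimated from the p-value distribution.  Peptides with q below the
screening threshold (default 0.05) are declared markers; the expected
number of false positives among them is ``q-threshold x #declared``.

Intensities are log2-transformed and quantile-normalized before presence
calling.  A peptide is called *present* in a sample when its normalized
intensity is observed and at least the quality threshold; missing values
are absent.  (The threshold direction is: at or above the threshold means
present — an intensity too low to trust does not count as an
identification.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarkerRecord", "ScreenResult",
    "quantile_normalize", "call_presence", "peptide_chisq", "bh_adjust",
    "storey_qvalues", "screen_markers", "screen_study", "classify_splicing",
    "contingency_chisq",
]

GROUPS = ("health", "cancer")

SPLICING_CLASSES = {
    "EXON": "single_exon",
    "E_E_SKIP": "exon_splicing",
    "E_E_NORMAL": "normal_exon",
    "E_I": "intron_retention_right",
    "I_E": "intron_retention_left",
}


@dataclass
class MarkerRecord:
    peptide: str
    health_present: int
    cancer_present: int
    n_health: int
    n_cancer: int
    chi2: float
    p: float
    p_adj: float = np.nan
    q: float = np.nan
    splicing_class: str | None = None

    @property
    def direction(self) -> str:
        """Group with the higher presence proportion (ties -> health)."""
        if self.cancer_present / self.n_cancer > self.health_present / self.n_health:
            return "cancer"
        return "health"


@dataclass
class ScreenResult:
    records: list[MarkerRecord]
    selected: list[MarkerRecord]
    alpha: float
    pi0: float

    @property
    def fpr(self) -> float:
        """Expected false positives among the declared markers."""
        return self.alpha * len(self.selected)

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "peptide": r.peptide,
            "health_present": r.health_present,
            "cancer_present": r.cancer_present,
            "n_health": r.n_health, "n_cancer": r.n_cancer,
            "chi2": r.chi2, "p": r.p, "p_adj": r.p_adj, "q": r.q,
            "direction": r.direction,
            "splicing_class": r.splicing_class,
            "selected": r in self.selected,
        } for r in self.records]
        return pd.DataFrame(rows)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (samples) of an intensity matrix.

    Each sample's observed values are replaced by the cross-sample mean of
    the order statistics at the matching quantile, so complete samples end
    up with identical value multisets.  Missing cells stay missing; with
    unequal numbers of observed values per sample the reference
    distribution is interpolated on a common quantile grid.
    """
    arr = m.to_numpy(dtype=float)
    n_obs = (~np.isnan(arr)).sum(axis=0)
    if (n_obs == 0).any():
        bad = m.columns[n_obs == 0].tolist()
        raise ValueError(f"samples with no observed intensities: {bad}")

    grid = np.linspace(0.0, 1.0, arr.shape[0])
    ref = np.zeros_like(grid)
    for j in range(arr.shape[1]):
        col = np.sort(arr[~np.isnan(arr[:, j]), j])
        if len(col) == 1:
            ref += col[0]
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, len(col)), col)
    ref /= arr.shape[1]

    out = np.full_like(arr, np.nan)
    for j in range(arr.shape[1]):
        mask = ~np.isnan(arr[:, j])
        vals = arr[mask, j]
        # average ranks over ties keeps tied inputs tied in the output
        ranks = stats.rankdata(vals, method="average") - 1.0
        denom = max(len(vals) - 1, 1)
        out[mask, j] = np.interp(ranks / denom, grid, ref)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def call_presence(m: pd.DataFrame, threshold: float | str = "auto") -> pd.DataFrame:
    """Binarize normalized intensities against a quality threshold.

    ``threshold="auto"`` uses the 5th percentile of all observed values.
    A cell is present iff observed and >= threshold.
    """
    arr = m.to_numpy(dtype=float)
    if threshold == "auto":
        observed = arr[~np.isnan(arr)]
        if observed.size == 0:
            raise ValueError("matrix has no observed intensities")
        threshold = float(np.percentile(observed, 5))
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    present = (~np.isnan(arr)) & (arr >= threshold)
    return pd.DataFrame(present, index=m.index, columns=m.columns)


def peptide_chisq(h_present: int, n_h: int, c_present: int, n_c: int
                  ) -> tuple[float, float]:
    """Pearson chi-square (df=1, no continuity correction) on the 2x2
    presence table.  Degenerate margins return (0, 1)."""
    if n_h <= 0 or n_c <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= h_present <= n_h and 0 <= c_present <= n_c):
        raise ValueError("presence counts exceed group sizes")
    a, b = h_present, n_h - h_present
    c, d = c_present, n_c - c_present
    n = n_h + n_c
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if c1 == 0 or c2 == 0:
        return 0.0, 1.0
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_pi0(pvalues, lambdas=None) -> float:
    """Estimate the null proportion pi0 from the p-value distribution.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on a grid
    of lambdas, a cubic trend is fitted and evaluated at the largest
    lambda, and the result is clamped to (0, 1].  For small inputs
    (m < 100) the raw estimate at lambda = 0.5 is used instead.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    if m < 100:
        pi0 = (p > 0.5).sum() / (m * 0.5)
    else:
        pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam))
                               for lam in lambdas])
        coef = np.polynomial.polynomial.polyfit(lambdas, pi0_lambda, deg=3)
        pi0 = float(np.polynomial.polynomial.polyval(lambdas.max(), coef))
    return float(min(max(pi0, 1.0 / m), 1.0))


def storey_qvalues(pvalues, lambdas=None) -> tuple[np.ndarray, float]:
    """Storey-Tibshirani q-values: q(p_(i)) = min_{j>=i} pi0 m p_(j) / j."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m < 2:
        raise ValueError("q-value estimation needs at least 2 p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    pi0 = storey_pi0(p, lambdas)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def screen_markers(records: list[MarkerRecord], alpha: float = 0.05,
                   lambdas=None) -> ScreenResult:
    """Attach adjusted p and q values and select markers at q < alpha."""
    if not records:
        return ScreenResult(records=[], selected=[], alpha=alpha, pi0=1.0)
    p = np.array([r.p for r in records])
    p_adj = bh_adjust(p)
    if p.size >= 2:
        q, pi0 = storey_qvalues(p, lambdas)
    else:
        q, pi0 = p_adj.copy(), 1.0
    for r, pa, qv in zip(records, p_adj, q):
        r.p_adj = float(pa)
        r.q = float(qv)
    selected = [r for r in records if r.q < alpha]
    return ScreenResult(records=records, selected=selected, alpha=alpha, pi0=pi0)


def screen_study(
    intensities: pd.DataFrame,
    groups: pd.Series | dict,
    alpha: float = 0.05,
    threshold: float | str = "auto",
    log2_input: bool = True,
    splicing_classes: dict | None = None,
) -> tuple[ScreenResult, pd.DataFrame]:
    """Full screen: log2 -> quantile normalize -> presence -> chi-square
    -> BH -> Storey q -> q < alpha.

    ``groups`` maps sample id to "health" or "cancer".  Returns the
    :class:`ScreenResult` and the presence matrix used.
    """
    groups = pd.Series(groups)
    missing = [s for s in intensities.columns if s not in groups.index]
    if missing:
        raise ValueError(f"samples without group labels: {missing}")
    bad = set(groups.unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {bad}")

    mat = intensities.copy()
    if log2_input:
        with np.errstate(invalid="ignore"):
            mat = np.log2(mat)
    normalized = quantile_normalize(mat)
    presence = call_presence(normalized, threshold)

    h_samples = [s for s in presence.columns if groups[s] == "health"]
    c_samples = [s for s in presence.columns if groups[s] == "cancer"]
    if not h_samples or not c_samples:
        raise ValueError("need at least one sample per group")
    n_h, n_c = len(h_samples), len(c_samples)

    records = []
    for pep in presence.index:
        h = int(presence.loc[pep, h_samples].sum())
        c = int(presence.loc[pep, c_samples].sum())
        chi2, p = peptide_chisq(h, n_h, c, n_c)
        records.append(MarkerRecord(
            peptide=str(pep), health_present=h, cancer_present=c,
            n_health=n_h, n_cancer=n_c, chi2=chi2, p=p,
            splicing_class=(splicing_classes or {}).get(str(pep))))
    return screen_markers(records, alpha=alpha), presence


def classify_splicing(jtype) -> str:
    """Map a junction type to its splicing marker class."""
    name = getattr(jtype, "value", jtype)
    try:
        return SPLICING_CLASSES[name]
    except KeyError:
        raise ValueError(f"unknown junction type: {jtype!r}") from None


def contingency_chisq(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, optional Yates correction.

    Returns ``(chi2, df, p)``.  Without correction this equals the closed
    form ``n (ad - bc)^2 / (R1 R2 C1 C2)`` exactly on integer tables.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=yates)
    return float(chi2), int(df), float(p)
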