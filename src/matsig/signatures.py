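"""Material signatures and correlation analyses.

A material's *signature* is its vector of mean attribute ratings.  This module
aggregates judgments to stimulus-level means, collapses them to material
signatures, computes attribute-attribute and image-statistic-attribute Pearson
correlation tables with Bonferroni-tiered significance stars, and compares two
signature tables cell-by-cell with a Wilcoxon signed-rank test.

Bonferroni tiers follow the convention alpha / n_tests for base alphas 0.05,
0.005 and 0.0005 (* / ** / ***): 45 attribute pairs, or 40 statistic x
attribute tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import StudyDesign

#: Base alpha levels (before Bonferroni division) for the *, **, *** tiers.
BASE_ALPHAS = (0.05, 0.005, 0.0005)


@dataclass
class CorrelationResult:
    """Pearson correlation table with Bonferroni significance tiers.

    ``tiers`` holds 0 (n.s.) to 3 (***) per cell; ``alphas`` are the
    Bonferroni-adjusted thresholds actually applied.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    tiers: pd.DataFrame
    alphas: tuple[float, float, float]
    n: int

    @property
    def square(self) -> bool:
        return self.r.shape[0] == self.r.shape[1] and list(self.r.index) == list(self.r.columns)


@dataclass(frozen=True)
class SignatureComparison:
    """Wilcoxon signed-rank comparison of two signature tables."""

    W: float                 # sum of ranks of positive differences
    n_pairs: int             # non-zero differences used
    z: float
    p_value: float
    all_zero: bool = False


def stimulus_means(records: pd.DataFrame, design: StudyDesign,
                   stimuli: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean rating per stimulus x attribute, averaged over raters and repetitions.

    Returns a DataFrame indexed by stimulus_id with a leading ``material``
    column followed by one column per attribute.  Missing stimulus/attribute
    cells raise.
    """
    table = records.pivot_table(index="stimulus_id", columns="attribute",
                                values="value", aggfunc="mean")
    missing_attrs = [a for a in design.attributes if a not in table.columns]
    if missing_attrs or table.isna().any().any():
        holes = table.isna().sum().sum() if not missing_attrs else "all"
        raise ValueError(f"incomplete records: missing attributes {missing_attrs}, "
                         f"{holes} empty stimulus/attribute cells")
    table = table[list(design.attributes)]
    if stimuli is not None:
        material = stimuli.set_index("stimulus_id")["material"].reindex(table.index)
    else:
        material = pd.Series([s.rsplit("_", 1)[0] for s in table.index], index=table.index)
    unknown = set(material) - set(design.materials)
    if unknown:
        raise ValueError(f"unknown material labels: {sorted(unknown)}")
    out = table.copy()
    out.insert(0, "material", material)
    return out


def attribute_matrix(means: pd.DataFrame) -> pd.DataFrame:
    """Numeric attribute columns of a stimulus-means table."""
    return means.drop(columns=["material"]) if "material" in means.columns else means


def signature_table(means: pd.DataFrame, design: StudyDesign | None = None) -> pd.DataFrame:
    """Material x attribute table of mean ratings (the material signatures)."""
    if "material" not in means.columns:
        raise ValueError("means table lacks a 'material' column")
    table = means.groupby("material", sort=False).mean(numeric_only=True)
    if design is not None:
        unknown = set(table.index) - set(design.materials)
        if unknown:
            raise ValueError(f"unknown material labels: {sorted(unknown)}")
        table = table.reindex([m for m in design.materials if m in table.index])
    return table


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t-transform with df = n - 2."""
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def _tiers(p: pd.DataFrame, alphas: tuple[float, float, float]) -> pd.DataFrame:
    tiers = sum((p < a).astype(int) for a in alphas)
    return tiers


def attribute_correlations(means: pd.DataFrame,
                           base_alphas: tuple[float, float, float] = BASE_ALPHAS
                           ) -> CorrelationResult:
    """Attribute x attribute Pearson correlations over stimulus means.

    Tiers use Bonferroni division by the number of distinct attribute pairs
    (45 for 10 attributes).
    """
    X = attribute_matrix(means)
    if len(X) < 3:
        raise ValueError("need at least 3 stimuli")
    if (X.std(ddof=0) == 0).any():
        bad = list(X.columns[X.std(ddof=0) == 0])
        raise ValueError(f"zero-variance attribute columns: {bad}")
    n, k = X.shape
    r = X.corr(method="pearson")
    p = pd.DataFrame(_pearson_p(r.to_numpy(), n), index=r.index, columns=r.columns)
    np.fill_diagonal(p.values, 0.0)
    n_pairs = k * (k - 1) // 2
    alphas = tuple(a / n_pairs for a in base_alphas)
    return CorrelationResult(r=r, p=p, tiers=_tiers(p, alphas), alphas=alphas, n=n)


def imagestat_correlations(means: pd.DataFrame, stats: pd.DataFrame,
                           scope: str = "global",
                           base_alphas: tuple[float, float, float] = BASE_ALPHAS):
    """Image-statistic x attribute correlations (4 x 10 table).

    ``stats`` is indexed by stimulus_id (or has a ``stimulus_id`` column) with
    one column per statistic.  ``scope="global"`` correlates over all stimuli;
    ``scope="per-material"`` returns ``{material: CorrelationResult}`` over
    each material's stimuli.  Bonferroni division uses the number of
    statistic x attribute tests (40).
    """
    if "stimulus_id" in stats.columns:
        stats = stats.set_index("stimulus_id")
    X = attribute_matrix(means)
    if not X.index.equals(stats.index):
        if set(X.index) != set(stats.index):
            raise ValueError("stimulus ids of means and stats tables do not align")
        stats = stats.reindex(X.index)
    n_tests = stats.shape[1] * X.shape[1]
    alphas = tuple(a / n_tests for a in base_alphas)

    def _one(xa: pd.DataFrame, st: pd.DataFrame) -> CorrelationResult:
        n = len(xa)
        if n < 3:
            raise ValueError("need at least 3 stimuli per correlation scope")
        r = pd.DataFrame(index=st.columns, columns=xa.columns, dtype=float)
        for s in st.columns:
            for a in xa.columns:
                r.loc[s, a] = np.corrcoef(st[s], xa[a])[0, 1]
        p = pd.DataFrame(_pearson_p(r.to_numpy(), n), index=r.index, columns=r.columns)
        return CorrelationResult(r=r, p=p, tiers=_tiers(p, alphas), alphas=alphas, n=n)

    if scope == "global":
        return _one(X, stats)
    if scope == "per-material":
        out = {}
        for m, idx in means.groupby("material", sort=False).groups.items():
            out[m] = _one(X.loc[idx], stats.loc[idx])
        return out
    raise ValueError("scope must be 'global' or 'per-material'")


def wilcoxon_signed_rank(differences: np.ndarray) -> SignatureComparison:
    """Wilcoxon signed-rank test with normal-approximation p-value.

    Zero differences are dropped; tied absolute differences receive midranks;
    the statistic W is the sum of ranks of positive differences.  The
    two-sided p uses the normal approximation with tie correction.
    """
    d = np.asarray(differences, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return SignatureComparison(W=0.0, n_pairs=0, z=0.0, p_value=1.0, all_zero=True)
    ranks = sps.rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var == 0:
        return SignatureComparison(W=W, n_pairs=n, z=0.0, p_value=1.0, all_zero=False)
    z = (W - mean) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return SignatureComparison(W=W, n_pairs=n, z=float(z), p_value=float(min(p, 1.0)))


def compare_signatures(a: pd.DataFrame, b: pd.DataFrame,
                       pairing: list[tuple[tuple[str, str], tuple[str, str]]] | None = None
                       ) -> SignatureComparison:
    """Compare two signature tables on their shared cells.

    ``pairing`` maps cells of ``a`` to cells of ``b`` as
    ``((material_a, attribute_a), (material_b, attribute_b))`` tuples; by
    default all shared (material, attribute) cells are paired identically.
    At least 6 pairs are required.
    """
    if pairing is None:
        mats = [m for m in a.index if m in b.index]
        attrs = [c for c in a.columns if c in b.columns]
        pairing = [((m, c), (m, c)) for m in mats for c in attrs]
    if len(pairing) < 6:
        raise ValueError(f"need at least 6 shared cells, got {len(pairing)}")
    diffs = np.array([a.loc[ka[0], ka[1]] - b.loc[kb[0], kb[1]] for ka, kb in pairing])
    return wilcoxon_signed_rank(diffs)
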