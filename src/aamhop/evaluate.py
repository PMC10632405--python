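"""Screen evaluation: structural novelty, enrichment, and contingency stats.

Covers the standard virtual-screening report: Morgan-fingerprint Tanimoto
coefficients against the reference (low values among hits indicate scaffold
hopping), the extraction rate (fraction of known same-target compounds
recovered), the enrichment factor (predicted over random hit rate), the
chi-square test of independence on 2x2 hit/function contingency tables
(Pearson, no continuity correction), and an unpaired two-tailed t-test with
an F-test gate choosing pooled versus unequal-variance form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy import stats

from .descriptors import Molecule
from .screening import ScreeningRecord

MORGAN_RADIUS = 2
MORGAN_NBITS = 2048

_fpgen = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=MORGAN_NBITS
)


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows = (hits, non-hits), columns =
    (same function, different function)."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("hits", "non-hits")
    col_labels: tuple[str, str] = ("same function", "different function")

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (2, 2):
            raise ValueError("contingency table must be 2x2")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            c = c.astype(float)
            if np.any(c < 0) or np.any(c != np.round(c)):
                raise ValueError("counts must be non-negative integers")
        if c.sum() < 1:
            raise ValueError("grand total must be at least 1")
        self.counts = np.asarray(self.counts, dtype=int)


@dataclass
class EnrichmentReport:
    random_hit_rate: float
    predicted_hit_rate: float
    ef: float
    library_total: int
    library_same_target: int
    hits_total: int
    hits_same_target: int


def tanimoto_morgan(a: Molecule | Chem.Mol, b: Molecule | Chem.Mol) -> float:
    """Tanimoto coefficient of radius-2, 2048-bit Morgan fingerprints."""
    from rdkit import DataStructs

    ma = a.rdkit_mol if isinstance(a, Molecule) else a
    mb = b.rdkit_mol if isinstance(b, Molecule) else b
    fa = _fpgen.GetFingerprint(ma)
    fb = _fpgen.GetFingerprint(mb)
    return float(DataStructs.TanimotoSimilarity(fa, fb))


def extraction_rate(hits_same_target: int, reported_same_target: int) -> float:
    """100·B/A as a percentage, one decimal: the fraction of the known
    same-target compounds (A) recovered as hits (B)."""
    B, A = hits_same_target, reported_same_target
    if A < 1:
        raise ValueError("the reported same-target count A must be >= 1")
    if not 0 <= B <= A:
        raise ValueError(f"need 0 <= B <= A, got B={B}, A={A}")
    return round(100.0 * B / A, 1)


def enrichment_factor(
    library_total: int,
    library_same_target: int,
    hits_total: int,
    hits_same_target: int,
) -> EnrichmentReport:
    """Predicted hit rate divided by random hit rate.

    The random rate is the same-target fraction of the (charge-matched)
    library; the predicted rate is the same-target fraction of the hits.
    """
    if library_total < 1 or hits_total < 1:
        raise ValueError("totals must be >= 1")
    if not 0 <= library_same_target <= library_total:
        raise ValueError("library same-target count out of range")
    if not 0 <= hits_same_target <= hits_total:
        raise ValueError("hit same-target count out of range")
    if library_same_target == 0:
        raise ValueError("EF undefined: no same-target compounds in the library")
    random_rate = library_same_target / library_total
    predicted_rate = hits_same_target / hits_total
    return EnrichmentReport(
        random_hit_rate=random_rate,
        predicted_hit_rate=predicted_rate,
        ef=predicted_rate / random_rate,
        library_total=library_total,
        library_same_target=library_same_target,
        hits_total=hits_total,
        hits_same_target=hits_same_target,
    )


def chi_square_independence(
    table: ContingencyTable2x2 | np.ndarray,
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, df = 1, two-sided p.

    No Yates continuity correction is applied.
    """
    counts = table.counts if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    counts = np.asarray(counts, dtype=float)
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: a marginal total is zero")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class TwoSampleTestResult:
    f_pvalue: float
    t_statistic: float
    t_pvalue: float
    equal_variance_assumed: bool


def two_sample_test(
    x, y, f_alpha: float = 0.05
) -> TwoSampleTestResult:
    """Unpaired two-tailed t-test with an F-test variance gate.

    A two-tailed F-test on the sample variances at ``f_alpha`` chooses
    between the pooled (equal-variance) and Welch forms.  Two constant,
    equal samples return p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if np.mean(x) == np.mean(y):
            return TwoSampleTestResult(1.0, 0.0, 1.0, True)
        raise ValueError("degenerate samples: zero variance, different means")
    if vy == 0 or vx == 0:
        f_p = 0.0
    else:
        f = vx / vy
        p_upper = stats.f.sf(f, x.size - 1, y.size - 1)
        f_p = 2.0 * min(p_upper, 1.0 - p_upper)
    equal_var = f_p >= f_alpha
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return TwoSampleTestResult(float(f_p), float(t), float(p), bool(equal_var))


def load_annotations(path) -> pd.DataFrame:
    """Annotation TSV: compound_id, known_targets (';'-separated),
    same_target (0/1), same_function (0/1/NA)."""
    df = pd.read_csv(path, sep="\t", dtype={"compound_id": str})
    required = {"compound_id", "same_target"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def similarity_vs_tanimoto(
    records: list[ScreeningRecord],
    annotations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-compound (tanimoto, similarity, hit, same-target) rows, one per
    screened compound, suitable for the structural-novelty scatter plot."""
    rows = []
    ann = None
    if annotations is not None:
        ann = annotations.set_index("compound_id")
    for r in records:
        same_target = np.nan
        if ann is not None and r.compound_id in ann.index:
            same_target = ann.loc[r.compound_id, "same_target"]
        rows.append(
            (r.compound_id, r.tanimoto_to_reference, r.aam_similarity,
             r.is_hit, same_target)
        )
    return pd.DataFrame(
        rows,
        columns=["compound_id", "tanimoto", "aam_similarity", "is_hit",
                 "same_target"],
    )


def hit_function_table(
    records: list[ScreeningRecord], annotations: pd.DataFrame
) -> ContingencyTable2x2:
    """Cross-tabulate hit status against same-function annotations.

    Compounds without a same_function label (e.g. modulators with neither an
    agonist nor an antagonist annotation) are excluded.
    """
    if "same_function" not in annotations.columns:
        raise ValueError("annotations lack a same_function column")
    ann = annotations.set_index("compound_id")["same_function"]
    counts = np.zeros((2, 2), dtype=int)
    for r in records:
        if r.compound_id not in ann.index:
            continue
        val = ann.loc[r.compound_id]
        if pd.isna(val):
            continue
        row = 0 if r.is_hit else 1
        col = 0 if int(val) == 1 else 1
        counts[row, col] += 1
    return ContingencyTable2x2(counts=counts)
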