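"""Driver-group assignment, co-occurrence and allele-fraction statistics.

Works off a boolean alteration matrix (sample x "GENE:class"), where the
classes form a hierarchy: ``any`` ⊇ ``mutation_any`` ⊇ {``mutation_LoF``,
``mutation_WT``}, and ``any`` additionally includes homozygous deletions.
Co-occurrence and mutual exclusivity between alteration classes are tested
with two-sided Fisher exact tests (probability-summation convention) at the
study-wide 0.005 threshold; allele-fraction profiles are compared with
Kolmogorov–Smirnov tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALTERATION_CLASSES = (
    "mutation_LoF",
    "mutation_WT",
    "mutation_any",
    "homozygous_deletion",
    "any",
)

DRIVER_ORDER = (("APC", "A"), ("TP53", "P"), ("BRAF", "B"), ("KRAS", "K"))

NONSYNONYMOUS = ("missense", "nonsense", "frameshift", "inframe_indel",
                 "splice")


def build_alteration_matrix(
    mutations: Iterable,
    samples: Iterable,
    genes: Sequence[str],
    function_labels: Mapping[tuple[str, str, object], str] | None = None,
) -> pd.DataFrame:
    """Boolean sample x (gene, class) matrix plus a ``subtype`` column.

    ``function_labels`` optionally maps (sample_id, gene, protein_pos) to
    ``LoF``/``WT``; without it the LoF/WT columns stay False and only
    mutation_any / homozygous_deletion / any are populated.
    """
    sample_ids = [s.sample_id for s in samples]
    subtype = {s.sample_id: s.subtype_assigned for s in samples}
    cols = [f"{g}:{c}" for g in genes for c in ALTERATION_CLASSES]
    mat = pd.DataFrame(False, index=pd.Index(sample_ids, name="sample_id"),
                       columns=cols)
    for m in mutations:
        if m.gene not in genes or m.sample_id not in mat.index:
            continue
        if m.alteration_type == "homozygous_deletion":
            mat.loc[m.sample_id, f"{m.gene}:homozygous_deletion"] = True
            mat.loc[m.sample_id, f"{m.gene}:any"] = True
            continue
        if m.variant_class not in NONSYNONYMOUS:
            continue
        mat.loc[m.sample_id, f"{m.gene}:mutation_any"] = True
        mat.loc[m.sample_id, f"{m.gene}:any"] = True
        if function_labels is not None:
            label = function_labels.get(
                (m.sample_id, m.gene, m.protein_pos)
            )
            if label in ("LoF", "WT"):
                mat.loc[m.sample_id, f"{m.gene}:mutation_{label}"] = True
    mat["subtype"] = [subtype.get(s, "unknown") for s in mat.index]
    return mat


def assign_driver_group(
    alterations: Mapping[str, bool] | pd.Series,
) -> str:
    """Driver-group label from APC/TP53/BRAF/KRAS mutation status.

    Concatenates the letters A, P, B, K in that fixed order for each gene
    carrying a (non-deletion) mutation; ``N`` when none is mutated.
    Deletions are excluded from group labels.
    """
    label = ""
    for gene, letter in DRIVER_ORDER:
        key = f"{gene}:mutation_any"
        val = alterations.get(key, alterations.get(gene, False))
        if bool(val):
            label += letter
    return label or "N"


def driver_group_counts(matrix: pd.DataFrame) -> pd.Series:
    """Group sizes over a cohort; labels partition the samples."""
    labels = matrix.apply(assign_driver_group, axis=1)
    return labels.value_counts()


@dataclass
class ContingencyResult:
    """Two-sided Fisher exact test of a 2x2 alteration table.

    The odds ratio and its 95% CI use the Haldane–Anscombe 0.5 correction
    when any cell is zero; the p-value is from the uncorrected exact test.
    OR > 1 indicates co-occurrence, OR < 1 mutual exclusivity.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    ci_low: float
    ci_high: float
    untestable: bool = False

    def __post_init__(self):
        if not self.untestable:
            assert 0.0 <= self.p_value <= 1.0


def fisher_cooccurrence(
    a: int, b: int, c: int, d: int, z: float = 1.959963984540054
) -> ContingencyResult:
    """Fisher exact co-occurrence test on counts (both, a-only, b-only, neither)."""
    table = ((a, b), (c, d))
    if min(a + b, c + d, a + c, b + d) == 0:
        return ContingencyResult(
            table=table, odds_ratio=math.nan, p_value=math.nan,
            ci_low=math.nan, ci_high=math.nan, untestable=True,
        )
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        ah, bh, ch, dh = float(a), float(b), float(c), float(d)
    or_corr = (ah * dh) / (bh * ch)
    se = math.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    return ContingencyResult(
        table=table,
        odds_ratio=or_corr,
        p_value=float(p),
        ci_low=or_corr * math.exp(-z * se),
        ci_high=or_corr * math.exp(z * se),
    )


def test_cooccurrence(
    matrix: pd.DataFrame,
    a: tuple[str, str],
    b: tuple[str, str],
    stratum: str | None = None,
) -> ContingencyResult:
    """Co-occurrence / mutual exclusivity of two alteration classes.

    ``a`` and ``b`` are (gene, class) pairs; ``stratum`` restricts to one
    MS subtype. Degenerate margins (a feature always or never altered in
    the stratum) yield an ``untestable`` result rather than an error.
    """
    sub = matrix if stratum is None else matrix[matrix["subtype"] == stratum]
    if len(sub) == 0:
        raise ValueError(f"stratum {stratum!r} is empty")
    xa = sub[f"{a[0]}:{a[1]}"].to_numpy(dtype=bool)
    xb = sub[f"{b[0]}:{b[1]}"].to_numpy(dtype=bool)
    both = int(np.sum(xa & xb))
    a_only = int(np.sum(xa & ~xb))
    b_only = int(np.sum(~xa & xb))
    neither = int(np.sum(~xa & ~xb))
    return fisher_cooccurrence(both, a_only, b_only, neither)


# ---------------------------------------------------------------------------
# Allele fractions
# ---------------------------------------------------------------------------

def normalize_af(af_target: float, af_reference: float) -> float:
    """Ratio of a target mutation's allele fraction to a same-tumor driver's.

    Normalizing by a clonal driver from the same tumor cancels purity and
    ploidy, so the ratio reflects relative timing: ~1 for clonal events,
    <1 for subclonal ones.
    """
    for name, v in (("af_target", af_target), ("af_reference", af_reference)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {v}")
    return af_target / af_reference


def normalize_af_batch(
    records: Iterable[tuple[str, float, float | None]],
) -> pd.DataFrame:
    """Vectorized normalization; rows with missing/zero reference dropped.

    Each record is (sample_id, af_target, af_reference_driver or None).
    The number of dropped rows is reported in ``attrs['n_dropped']``.
    """
    rows, dropped = [], 0
    for sid, af_t, af_r in records:
        if af_r is None or af_r <= 0:
            dropped += 1
            continue
        rows.append(
            {
                "sample_id": sid,
                "af_target": af_t,
                "af_reference_driver": af_r,
                "normalized_af": normalize_af(af_t, af_r),
            }
        )
    out = pd.DataFrame(
        rows, columns=["sample_id", "af_target", "af_reference_driver",
                       "normalized_af"]
    )
    out.attrs["n_dropped"] = dropped
    return out


def compare_af(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov comparison of AF distributions.

    Uses the exact null distribution when both groups have n <= 25, the
    asymptotic one otherwise. Returns (D, p).
    """
    g1, g2 = np.asarray(group1, float), np.asarray(group2, float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need at least 2 observations")
    method = "exact" if (len(g1) <= 25 and len(g2) <= 25) else "asymp"
    res = stats.ks_2samp(g1, g2, method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Stage-stratified frequencies
# ---------------------------------------------------------------------------

def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (math.nan, math.nan)
    res = stats.binomtest(k, n).proportion_ci(
        confidence_level=conf, method="wilson"
    )
    return float(res.low), float(res.high)


def frequency_by_stratum(
    matrix: pd.DataFrame,
    target: tuple[str, str],
    strata: Mapping[str, pd.Series | np.ndarray],
) -> pd.DataFrame:
    """Alteration frequency with Wilson 95% CI per stratum, plus Fisher tests.

    ``strata`` maps a stratum name to a boolean mask over the matrix rows
    (e.g. stage I+II within MT-L). Pairwise cross-stratum equality tests
    (Fisher exact) are attached in ``attrs['pairwise_p']``.
    """
    col = f"{target[0]}:{target[1]}"
    rows = {}
    for name, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        k = int(matrix.loc[mask, col].sum())
        lo, hi = wilson_interval(k, n)
        rows[name] = {
            "n": n, "altered": k,
            "frequency": k / n if n else math.nan,
            "ci_low": lo, "ci_high": hi,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    names = list(strata)
    pairwise = {}
    for i, n1 in enumerate(names):
        for n2 in names[i + 1:]:
            r1, r2 = rows[n1], rows[n2]
            if r1["n"] == 0 or r2["n"] == 0:
                pairwise[(n1, n2)] = math.nan
                continue
            _, p = stats.fisher_exact(
                [
                    [r1["altered"], r1["n"] - r1["altered"]],
                    [r2["altered"], r2["n"] - r2["altered"]],
                ]
            )
            pairwise[(n1, n2)] = float(p)
    out.attrs["pairwise_p"] = pairwise
    return out
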