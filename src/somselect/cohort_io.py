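"""Cohort ingestion and microsatellite-subtype assignment.

Loads somatic mutation tables (MAF-like TSV, or VCF with protein
annotations) and per-tumor sample tables, validates them into typed
records, and assigns each tumor one of three composite
microsatellite/mutation-burden subtypes:

* ``MT-L``  — microsatellite stable or low tumor mutational burden (TMB),
* ``MT-H``  — microsatellite unstable or TMB in the likely-MSI window,
* ``MSS-htmb`` — microsatellite stable hypermutators (TMB above the window,
  typically POLE/POLD-driven).

For targeted panels that report neither TMB nor MS status, a small
conditional-inference-style threshold tree can be trained on labeled
reference samples (features: copy-number-altered fraction, mismatch-repair
gene mutation, raw mutation count) and used to impute MSS/MSI-H.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from .config import default_config

VARIANT_CLASSES = {
    "missense",
    "nonsense",
    "synonymous",
    "frameshift",
    "inframe_indel",
    "splice",
    "other",
}

SUBTYPES = ("MT-L", "MT-H", "MSS-htmb")

_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class RowError(ValueError):
    """A row failed validation; carries the 1-based data row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass
class MutationRecord:
    """One somatic variant call in one tumor."""

    sample_id: str
    gene: str
    chrom: str = ""
    pos: int | None = None
    ref: str = ""
    alt: str = ""
    variant_class: str = "other"
    protein_pos: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    allele_fraction: float | None = None
    alteration_type: str = "mutation"

    def __post_init__(self):
        if self.variant_class not in VARIANT_CLASSES:
            self.variant_class = "other"
        if self.allele_fraction is not None and not (
            0.0 <= self.allele_fraction <= 1.0
        ):
            raise ValueError(
                f"allele_fraction {self.allele_fraction} outside [0, 1]"
            )


@dataclass
class SampleRecord:
    """One tumor's clinical and assay metadata."""

    sample_id: str
    ms_status_known: str = "unknown"  # MSS | MSI-H | unknown
    tmb: float | None = None
    sensor_score: float | None = None
    mantis_score: float | None = None
    panel_id: str = ""
    cna_fraction: float | None = None
    mmr_mutated: bool | None = None
    mutation_count: int | None = None
    stage: str = "unknown"  # I | II | III | IV | unknown
    subtype_assigned: str = "unknown"

    def __post_init__(self):
        for name in ("tmb", "sensor_score", "mantis_score"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.cna_fraction is not None and not (0 <= self.cna_fraction <= 1):
            raise ValueError(f"cna_fraction {self.cna_fraction} outside [0,1]")


# ---------------------------------------------------------------------------
# Subtype assignment
# ---------------------------------------------------------------------------

def classify_ms_status(sample: SampleRecord, config: dict | None = None) -> str:
    """Assign the composite MS subtype for one tumor.

    Precedence: TMB above the hypermutator cutoff forces ``MSS-htmb``
    regardless of other evidence; otherwise a known MS status wins over
    TMB imputation (configurable via ``known_status_wins``); otherwise TMB
    in [tmb_low, tmb_htmb] means ``MT-H`` and below means ``MT-L``; with no
    TMB, an MSI-score (sensor/mantis) at or above its cutoff means ``MT-H``
    and below means ``MT-L``. TMB intervals are half-open:
    MT-L = [0, 16), MT-H = [16, 100], MSS-htmb = (100, inf).
    """
    cfg = config or default_config()
    thr = cfg["thresholds"]
    tmb, sensor, mantis = sample.tmb, sample.sensor_score, sample.mantis_score
    known = sample.ms_status_known

    if tmb is not None and tmb < 0:
        raise ValueError(f"negative tmb: {tmb}")

    if tmb is not None and tmb > thr["tmb_htmb"]:
        return "MSS-htmb"
    if known in ("MSS", "MSI-H") and cfg.get("known_status_wins", True):
        return "MT-H" if known == "MSI-H" else "MT-L"
    if tmb is not None:
        return "MT-H" if tmb >= thr["tmb_low"] else "MT-L"
    if known in ("MSS", "MSI-H"):
        return "MT-H" if known == "MSI-H" else "MT-L"
    if sensor is not None:
        return "MT-H" if sensor >= thr["sensor"] else "MT-L"
    if mantis is not None:
        return "MT-H" if mantis >= thr["mantis"] else "MT-L"
    return "unknown"


def assign_subtypes(
    samples: Iterable[SampleRecord], config: dict | None = None
) -> list[SampleRecord]:
    """Return copies of *samples* with ``subtype_assigned`` filled in."""
    return [
        replace(s, subtype_assigned=classify_ms_status(s, config))
        for s in samples
    ]


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

MUTATION_COLUMNS = {
    "sample_id": "sample_id",
    "gene": "gene",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "variant_class": "variant_class",
    "protein_change": "protein_change",
    "protein_pos": "protein_pos",
    "aa_ref": "aa_ref",
    "aa_alt": "aa_alt",
    "allele_fraction": "allele_fraction",
    "alteration_type": "alteration_type",
}

SAMPLE_COLUMNS = {
    "sample_id": "sample_id",
    "ms_status_known": "ms_status_known",
    "tmb": "tmb",
    "sensor_score": "sensor_score",
    "mantis_score": "mantis_score",
    "panel_id": "panel_id",
    "cna_fraction": "cna_fraction",
    "mmr_mutated": "mmr_mutated",
    "mutation_count": "mutation_count",
    "stage": "stage",
    "subtype_assigned": "subtype_assigned",
}

_REQUIRED_MUTATION = ("sample_id", "gene")
_REQUIRED_SAMPLE = ("sample_id",)

_PROTEIN_RE = re.compile(
    r"^(?:p\.)?(?P<ref>[A-Z\*]|[A-Z][a-z]{2})(?P<pos>\d+)"
    r"(?P<alt>[A-Z\*=]|[A-Z][a-z]{2}|fs.*|del.*|ins.*|dup.*)?$"
)


def parse_protein_change(text: str) -> tuple[int | None, str | None, str | None]:
    """Parse ``R130Q`` / ``p.Arg130Ter`` style strings into (pos, ref, alt)."""
    if not text or (isinstance(text, float) and np.isnan(text)):
        return None, None, None
    m = _PROTEIN_RE.match(str(text).strip())
    if not m:
        return None, None, None

    def one(code: str | None) -> str | None:
        if code is None:
            return None
        if len(code) == 3 and code in _AA3TO1:
            return _AA3TO1[code]
        if len(code) == 1:
            return code if code != "=" else None
        return None  # fs/del/ins suffixes carry no single target residue

    return int(m.group("pos")), one(m.group("ref")), one(m.group("alt"))


def _opt_float(val) -> float | None:
    if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
        return None
    return float(val)


def _opt_int(val) -> int | None:
    v = _opt_float(val)
    return None if v is None else int(v)


def _opt_bool(val) -> bool | None:
    if val is None or val == "" or (isinstance(val, float) and np.isnan(val)):
        return None
    if isinstance(val, (bool, np.bool_)):
        return bool(val)
    return str(val).strip().lower() in ("1", "true", "yes", "t")


def _check_columns(df: pd.DataFrame, colmap: dict, required: Sequence[str],
                   what: str) -> None:
    for key in required:
        col = colmap.get(key, key)
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing column '{col}'")


def load_mutations(
    path: str | Path, column_map: dict | None = None
) -> list[MutationRecord]:
    """Load a MAF-like TSV (or annotated VCF) into MutationRecords.

    Unknown variant classes are mapped to ``other``. A record whose amino
    acids are identical but whose class claims missense is rewritten to
    synonymous with a warning — panel annotations occasionally disagree
    with their own protein strings.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _load_mutations_vcf(path)
    cmap = {**MUTATION_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_columns(df, cmap, _REQUIRED_MUTATION, "mutation")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        def get(key, default=""):
            return row.get(cmap.get(key, key), default)

        ppos = aa_ref = aa_alt = None
        if get("protein_pos"):
            try:
                ppos = _opt_int(get("protein_pos"))
            except ValueError as exc:
                raise RowError(i, f"malformed protein_pos: {exc}") from exc
            aa_ref = get("aa_ref") or None
            aa_alt = get("aa_alt") or None
        elif get("protein_change"):
            ppos, aa_ref, aa_alt = parse_protein_change(get("protein_change"))
        try:
            pos = _opt_int(get("pos"))
        except ValueError as exc:
            raise RowError(i, f"malformed genomic coordinate: {exc}") from exc
        vclass = get("variant_class", "other") or "other"
        if vclass not in VARIANT_CLASSES:
            vclass = "other"
        if (
            vclass == "missense"
            and aa_ref is not None
            and aa_alt is not None
            and aa_ref == aa_alt
        ):
            warnings.warn(
                f"row {i}: missense call with aa_ref == aa_alt "
                f"({aa_ref}{ppos}); rewriting class to synonymous",
                stacklevel=2,
            )
            vclass = "synonymous"
        try:
            records.append(
                MutationRecord(
                    sample_id=str(get("sample_id")),
                    gene=str(get("gene")),
                    chrom=str(get("chrom")),
                    pos=pos,
                    ref=str(get("ref")),
                    alt=str(get("alt")),
                    variant_class=vclass,
                    protein_pos=ppos,
                    aa_ref=aa_ref,
                    aa_alt=aa_alt,
                    allele_fraction=_opt_float(get("allele_fraction") or None),
                    alteration_type=get("alteration_type") or "mutation",
                )
            )
        except ValueError as exc:
            raise RowError(i, str(exc)) from exc
    return records


def _load_mutations_vcf(path: Path) -> list[MutationRecord]:
    """Minimal VCF reader: protein annotations from an ANN/CSQ INFO field."""
    records: list[MutationRecord] = []
    csq_fields: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##INFO=<ID=CSQ") or line.startswith("##INFO=<ID=ANN"):
                m = re.search(r"Format: ([^\"]+)", line)
                if m:
                    csq_fields = [f.strip() for f in m.group(1).split("|")]
                continue
            if line.startswith("#") or not line:
                continue
            parts = line.split("\t")
            chrom, pos, _id, ref, alt = parts[:5]
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "")
                for kv in parts[7].split(";")
            )
            sample = info.get("SAMPLE", parts[2] if parts[2] != "." else "")
            gene, vclass, ppos, aa_ref, aa_alt = "", "other", None, None, None
            ann = info.get("CSQ") or info.get("ANN") or ""
            if ann and csq_fields:
                vals = dict(zip(csq_fields, ann.split(",")[0].split("|")))
                gene = vals.get("SYMBOL", vals.get("Gene_Name", ""))
                vclass = _map_consequence(vals.get("Consequence",
                                                   vals.get("Annotation", "")))
                ppos, aa_ref, aa_alt = parse_protein_change(
                    vals.get("HGVSp", vals.get("HGVS.p", "")).split(":")[-1]
                )
            af = info.get("AF")
            records.append(
                MutationRecord(
                    sample_id=sample,
                    gene=gene,
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    variant_class=vclass,
                    protein_pos=ppos,
                    aa_ref=aa_ref,
                    aa_alt=aa_alt,
                    allele_fraction=float(af) if af else None,
                )
            )
    return records


def _map_consequence(term: str) -> str:
    term = term.lower()
    if "missense" in term:
        return "missense"
    if "stop_gained" in term or "nonsense" in term:
        return "nonsense"
    if "synonymous" in term:
        return "synonymous"
    if "frameshift" in term:
        return "frameshift"
    if "inframe" in term:
        return "inframe_indel"
    if "splice" in term:
        return "splice"
    return "other"


def load_samples(
    path: str | Path, column_map: dict | None = None
) -> list[SampleRecord]:
    cmap = {**SAMPLE_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _check_columns(df, cmap, _REQUIRED_SAMPLE, "sample")
    records = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        def get(key):
            return row.get(cmap.get(key, key), "") or None

        try:
            records.append(
                SampleRecord(
                    sample_id=str(get("sample_id")),
                    ms_status_known=get("ms_status_known") or "unknown",
                    tmb=_opt_float(get("tmb")),
                    sensor_score=_opt_float(get("sensor_score")),
                    mantis_score=_opt_float(get("mantis_score")),
                    panel_id=get("panel_id") or "",
                    cna_fraction=_opt_float(get("cna_fraction")),
                    mmr_mutated=_opt_bool(get("mmr_mutated")),
                    mutation_count=_opt_int(get("mutation_count")),
                    stage=get("stage") or "unknown",
                    subtype_assigned=get("subtype_assigned") or "unknown",
                )
            )
        except ValueError as exc:
            raise RowError(i, str(exc)) from exc
    return records


def load_cohort(
    mutations_path: str | Path,
    samples_path: str | Path,
    column_map: dict | None = None,
) -> tuple[list[MutationRecord], list[SampleRecord]]:
    """Load and validate a mutation table plus its sample table."""
    cm = (column_map or {}).get("mutations", column_map)
    sm = (column_map or {}).get("samples", None)
    return load_mutations(mutations_path, cm), load_samples(samples_path, sm)


def write_cohort(
    mutations: Iterable[MutationRecord],
    samples: Iterable[SampleRecord],
    mutations_path: str | Path,
    samples_path: str | Path,
) -> None:
    """Write records back to the canonical TSV layout (round-trip safe)."""
    mdf = pd.DataFrame([vars(m) for m in mutations])
    sdf = pd.DataFrame([vars(s) for s in samples])
    for df in (mdf, sdf):
        for col in df.columns:
            if df[col].dtype == object:
                df[col] = df[col].where(df[col].notna(), "")
    mdf.to_csv(mutations_path, sep="\t", index=False)
    sdf.to_csv(samples_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Threshold tree (conditional-inference-style recursive partitioning)
# ---------------------------------------------------------------------------

TREE_FEATURES = ("cna_fraction", "mmr_mutated", "mutation_count")


@dataclass
class TreeNode:
    """Internal split node: goes left when feature <= cutoff."""

    feature: str
    cutoff: float
    p_value: float
    left: "TreeNode | TreeLeaf"
    right: "TreeNode | TreeLeaf"


@dataclass
class TreeLeaf:
    label: str  # MSS | MSI-H
    n: int = 0


@dataclass
class ThresholdTree:
    """Recursive threshold partitioner for MSS/MSI-H imputation.

    Grown by, at each node, choosing the feature whose association with the
    label has the smallest permutation p-value, splitting only when that
    p-value beats ``alpha``, with an exhaustive scan over candidate cutoffs
    for the chosen feature. Cutoff ties are broken at the midpoint of the
    widest separating gap so the fitted cutoff is deterministic.
    """

    root: TreeNode | TreeLeaf = field(default_factory=lambda: TreeLeaf("MSS"))
    alpha: float = 0.001
    features: tuple[str, ...] = TREE_FEATURES

    def predict(self, sample: SampleRecord) -> str:
        node = self.root
        while isinstance(node, TreeNode):
            val = getattr(sample, node.feature, None)
            if val is None:
                raise ValueError(
                    f"sample {sample.sample_id!r} lacks feature "
                    f"'{node.feature}' required by the threshold tree"
                )
            node = node.left if float(val) <= node.cutoff else node.right
        return node.label

    def depth(self) -> int:
        def d(node):
            if isinstance(node, TreeLeaf):
                return 0
            return 1 + max(d(node.left), d(node.right))

        return d(self.root)


def _assoc_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute point-biserial-type statistic between feature and binary label."""
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return abs(np.corrcoef(x, y)[0, 1]) * np.sqrt(len(x))


def _permutation_p(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    obs = _assoc_statistic(x, y)
    if obs == 0.0:
        return 1.0
    count = 0
    yp = y.copy()
    for _ in range(n_perm):
        rng.shuffle(yp)
        if _assoc_statistic(x, yp) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def best_split(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exhaustive cutoff scan; returns (cutoff, criterion).

    Criterion is the chi-square statistic of the 2x2 (side x label) table.
    Among cutoffs attaining the maximum, the midpoint of the widest gap
    between adjacent distinct feature values is chosen.
    """
    xs = np.unique(x)
    if len(xs) < 2:
        return float(xs[0]), 0.0
    candidates = (xs[:-1] + xs[1:]) / 2.0
    gaps = xs[1:] - xs[:-1]
    n = len(x)
    best_stat, best_gap, best_cut = -1.0, -1.0, candidates[0]
    for cut, gap in zip(candidates, gaps):
        left = x <= cut
        a = np.sum(left & (y == 1))
        b = np.sum(left & (y == 0))
        c = np.sum(~left & (y == 1))
        d = np.sum(~left & (y == 0))
        row1, row2, col1, col2 = a + b, c + d, a + c, b + d
        if min(row1, row2, col1, col2) == 0:
            stat = 0.0
        else:
            exp = np.array(
                [row1 * col1, row1 * col2, row2 * col1, row2 * col2],
                dtype=float,
            ) / n
            obs = np.array([a, b, c, d], dtype=float)
            stat = float(np.sum((obs - exp) ** 2 / exp))
        if stat > best_stat + 1e-12 or (
            abs(stat - best_stat) <= 1e-12 and gap > best_gap
        ):
            best_stat, best_gap, best_cut = stat, gap, float(cut)
    return best_cut, best_stat


def fit_threshold_tree(
    samples: Sequence[SampleRecord],
    features: Sequence[str] = TREE_FEATURES,
    alpha: float = 0.001,
    n_perm: int = 10_000,
    seed: int | None = 0,
    min_node: int = 8,
) -> ThresholdTree:
    """Fit the MSS/MSI-H threshold tree on labeled reference samples."""
    if not features:
        raise ValueError("empty feature set")
    labeled = [s for s in samples if s.ms_status_known in ("MSS", "MSI-H")]
    if not labeled:
        raise ValueError("no labeled samples (ms_status_known)")
    cols = {}
    for f in features:
        vals = [getattr(s, f) for s in labeled]
        if any(v is None for v in vals):
            raise ValueError(f"feature '{f}' missing for some labeled samples")
        cols[f] = np.asarray(vals, dtype=float)
    y = np.asarray(
        [1 if s.ms_status_known == "MSI-H" else 0 for s in labeled], dtype=float
    )
    rng = np.random.default_rng(seed)

    def grow(idx: np.ndarray) -> TreeNode | TreeLeaf:
        yi = y[idx]
        majority = "MSI-H" if yi.mean() > 0.5 else "MSS"
        if len(idx) < min_node or yi.min() == yi.max():
            return TreeLeaf(majority, n=len(idx))
        pvals = {
            f: _permutation_p(cols[f][idx], yi, n_perm, rng) for f in features
        }
        fbest = min(sorted(pvals), key=lambda f: pvals[f])
        if pvals[fbest] >= alpha:
            return TreeLeaf(majority, n=len(idx))
        cutoff, stat = best_split(cols[fbest][idx], yi)
        left = idx[cols[fbest][idx] <= cutoff]
        right = idx[cols[fbest][idx] > cutoff]
        if len(left) == 0 or len(right) == 0 or stat == 0.0:
            return TreeLeaf(majority, n=len(idx))
        return TreeNode(fbest, cutoff, pvals[fbest], grow(left), grow(right))

    return ThresholdTree(
        root=grow(np.arange(len(labeled))),
        alpha=alpha,
        features=tuple(features),
    )


def predict_ms_panel(tree: ThresholdTree, sample: SampleRecord) -> str:
    """Impute MSS/MSI-H for a panel sample from the fitted threshold tree."""
    return tree.predict(sample)
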