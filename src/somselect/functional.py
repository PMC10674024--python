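"""Functional classification of variants and selection statistics.

Combines deep-mutational-scanning scores (lipid phosphatase activity and
protein abundance, each scaled so wild type sits near 1) with clinical
database annotations to dichotomize amino-acid changes into loss-of-function
(LoF) versus functionally wild-type (WT) classes, corrects signature-based
codon predictions by the fraction of function-damaging changes each codon
can produce, compares the fit of corrected models to observed hotspot
profiles, and estimates dN/dS with the background mutability model as the
neutral expectation.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import default_config
from .mutability import (
    GeneModel,
    MutabilityProfile,
    pearson_statistic,
    pool_small_expectations,
    substitution_consequences,
)

DAMAGE_MODES = ("sign", "lpa", "abund", "lpa+ab", "lof")

TRUNCATING_CLASSES = ("nonsense", "frameshift")
NONTRUNCATING_CLASSES = ("missense", "inframe_indel")


@dataclass
class FunctionalScoreTable:
    """Per-substitution functional scores plus annotation overrides.

    ``scores`` maps (1-based codon, alt residue) to continuous lipid
    phosphatase activity (lpa) and abundance scores; ``annotations`` maps a
    variant string like ``R130Q`` to ``pathogenic``/``benign``;
    ``indel_impact`` maps an inframe-indel key to an impact score in [0, 1]
    (higher = more damaging).
    """

    scores: pd.DataFrame  # index (codon, aa_alt), columns lpa_score, abundance_score
    annotations: dict[str, str] = field(default_factory=dict)
    indel_impact: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.scores.index.names == ["codon", "aa_alt"]:
            self.scores = self.scores.set_index(["codon", "aa_alt"])
        self.scores = self.scores.sort_index()
        for col in ("lpa_score", "abundance_score"):
            self.scores[col] = self.scores[col].astype(float)
        vals = self.scores[["lpa_score", "abundance_score"]].to_numpy()
        if not np.all(np.isfinite(vals) | np.isnan(vals)):
            raise ValueError("scores must be finite (or NaN for missing)")

    def lookup(self, codon: int, aa_alt: str) -> tuple[float | None, float | None]:
        try:
            row = self.scores.loc[(codon, aa_alt)]
        except KeyError:
            return None, None
        if isinstance(row, pd.DataFrame):  # duplicate keys: first row wins
            row = row.iloc[0]
        lpa = row["lpa_score"]
        ab = row["abundance_score"]
        return (
            None if pd.isna(lpa) else float(lpa),
            None if pd.isna(ab) else float(ab),
        )

    def coverage(self, gene: GeneModel) -> float:
        """Fraction of accessible missense changes with at least one score."""
        classes, aa_alts = substitution_consequences(gene)
        total = have = 0
        seen = set()
        for site in range(gene.coding_length):
            cidx, _ = gene.codon_of_site(site)
            for ai in range(4):
                if classes[site, ai] != "mis":
                    continue
                key = (cidx, aa_alts[site, ai])
                if key in seen:
                    continue
                seen.add(key)
                total += 1
                lpa, ab = self.lookup(*key)
                if lpa is not None or ab is not None:
                    have += 1
        return have / total if total else 0.0

    @classmethod
    def from_tsv(
        cls,
        scores_path: str | Path,
        annotations_path: str | Path | None = None,
    ) -> "FunctionalScoreTable":
        df = pd.read_csv(scores_path, sep="\t")
        ann = {}
        if annotations_path is not None:
            adf = pd.read_csv(annotations_path, sep="\t")
            ann = dict(zip(adf["variant"].astype(str), adf["call"].astype(str)))
        return cls(scores=df, annotations=ann)


@dataclass
class FunctionClass:
    label: str  # LoF | WT | NA
    evidence: str  # annotation | lpa | abundance | indel_score | none

    def __post_init__(self):
        if self.label == "NA":
            assert self.evidence == "none"


def classify_function(
    codon: int,
    aa_alt: str | None,
    scores: FunctionalScoreTable,
    config: dict | None = None,
    indel_key: str | None = None,
) -> FunctionClass:
    """Dichotomize one amino-acid change (or inframe indel) as LoF/WT/NA.

    Precedence: clinical annotation > continuous scores > indel impact.
    A change is LoF when its activity OR abundance score falls below the
    respective cutoff; WT when every available score clears its cutoff;
    NA when no evidence channel fires.
    """
    cfg = config or default_config()
    if aa_alt is not None:
        variant = f"{aa_alt_key(codon, aa_alt, scores)}"
        call = scores.annotations.get(variant)
        if call == "pathogenic":
            return FunctionClass("LoF", "annotation")
        if call == "benign":
            return FunctionClass("WT", "annotation")
        lpa, ab = scores.lookup(codon, aa_alt)
        if lpa is not None and lpa < cfg["lpa_cutoff"]:
            return FunctionClass("LoF", "lpa")
        if ab is not None and ab < cfg["abundance_cutoff"]:
            return FunctionClass("LoF", "abundance")
        if lpa is not None or ab is not None:
            return FunctionClass("WT", "lpa" if lpa is not None else "abundance")
    if indel_key is not None:
        impact = scores.indel_impact.get(indel_key)
        if impact is not None:
            label = "LoF" if impact >= cfg["indel_impact_cutoff"] else "WT"
            return FunctionClass(label, "indel_score")
    return FunctionClass("NA", "none")


def aa_alt_key(codon: int, aa_alt: str, scores: FunctionalScoreTable) -> str:
    """Annotation lookup key; annotations are stored as e.g. ``R130Q``."""
    # The reference residue is not known to the score table; annotation keys
    # are matched on position + alternate residue when the full string is
    # not found.
    for key in scores.annotations:
        if key[1:-1].isdigit() and int(key[1:-1]) == codon and key[-1] == aa_alt:
            return key
    return f"{codon}{aa_alt}"


# ---------------------------------------------------------------------------
# Damage fractions and corrected profiles
# ---------------------------------------------------------------------------

@dataclass
class DamageProfile:
    """Per-codon fractions of nonsynonymous mass that is function-damaging.

    One column per mode: ``sign`` (identically 1 — no functional
    correction), ``lpa``, ``abund``, ``lpa+ab`` (damaging if either score
    fires) and ``lof`` (scores plus annotation overrides). Fractions are
    weighted by the background substitution probabilities, so a codon's
    coefficient answers: of the mutations this codon is *expected* to
    receive, what share damages the protein?
    """

    fractions: pd.DataFrame  # index codon, one column per mode

    def __getitem__(self, mode: str) -> pd.Series:
        return self.fractions[mode]


def _is_damaging(
    mode: str,
    codon: int,
    aa_alt: str,
    cls: str,
    scores: FunctionalScoreTable,
    cfg: dict,
) -> bool | None:
    """Damaging verdict for one substitution under one mode; None = no data."""
    if cls == "non":
        return True  # stop gains destroy the protein under every mode
    lpa, ab = scores.lookup(codon, aa_alt)
    if mode == "lpa":
        return None if lpa is None else lpa < cfg["lpa_cutoff"]
    if mode == "abund":
        return None if ab is None else ab < cfg["abundance_cutoff"]
    if mode == "lpa+ab":
        if lpa is None and ab is None:
            return None
        return (lpa is not None and lpa < cfg["lpa_cutoff"]) or (
            ab is not None and ab < cfg["abundance_cutoff"]
        )
    if mode == "lof":
        fc = classify_function(codon, aa_alt, scores, cfg)
        return None if fc.label == "NA" else fc.label == "LoF"
    raise ValueError(f"unknown damage mode {mode!r}")


def damage_fraction(
    profile: MutabilityProfile,
    gene: GeneModel,
    scores: FunctionalScoreTable,
    modes: Iterable[str] = DAMAGE_MODES,
    config: dict | None = None,
) -> DamageProfile:
    """Probability-weighted damaging fraction per codon, per mode.

    For each codon, f = sum of background probabilities of its damaging
    nonsynonymous substitutions / sum over all its scored nonsynonymous
    substitutions. Under the default NA handling, unscored substitutions are
    excluded from both sums; codons with no scored nonsynonymous mass get
    NaN.
    """
    cfg = config or default_config()
    na_as_wt = cfg.get("na_handling") == "wt"
    classes, aa_alts = substitution_consequences(gene)
    n = gene.protein_length
    out = pd.DataFrame(
        np.nan, index=pd.RangeIndex(1, n + 1, name="codon"), columns=list(modes)
    )
    num = {m: np.zeros(n) for m in out.columns if m != "sign"}
    den = {m: np.zeros(n) for m in out.columns if m != "sign"}
    for site in range(gene.coding_length):
        cidx, _ = gene.codon_of_site(site)
        for ai in range(4):
            cls = classes[site, ai]
            if cls not in ("mis", "non"):
                continue
            p = profile.p_site_alt[site, ai]
            for m in num:
                verdict = _is_damaging(m, cidx, aa_alts[site, ai], cls,
                                       scores, cfg)
                if verdict is None:
                    if na_as_wt:
                        den[m][cidx - 1] += p
                    continue
                den[m][cidx - 1] += p
                if verdict:
                    num[m][cidx - 1] += p
    for m in num:
        with np.errstate(invalid="ignore", divide="ignore"):
            out[m] = np.where(den[m] > 0, num[m] / den[m], np.nan)
    if "sign" in out.columns:
        out["sign"] = 1.0
    return DamageProfile(fractions=out)


def corrected_codon_profile(
    codon_table: pd.DataFrame, damage: DamageProfile, mode: str
) -> pd.Series:
    """Damage-corrected per-codon nonsynonymous expectation, renormalized.

    Adjusted p_c is proportional to (missense + truncating mass) times the
    codon's damaging fraction under ``mode``; ``sign`` applies no
    correction. Codons whose fraction is undefined (no scored substitution)
    keep their uncorrected mass.
    """
    base = (codon_table["p_missense"] + codon_table["p_truncating"]).astype(float)
    if mode == "sign":
        adj = base.copy()
    else:
        f = damage[mode].reindex(base.index).fillna(1.0)
        adj = base * f
    total = adj.sum()
    if total <= 0:
        raise ValueError(f"mode {mode!r} zeroes out the whole profile")
    return adj / total


def model_fit_comparison(
    observed_counts: Mapping[int, int] | np.ndarray,
    codon_table: pd.DataFrame,
    damage: DamageProfile,
    modes: Iterable[str] = DAMAGE_MODES,
    include_random_baseline: bool = True,
) -> pd.DataFrame:
    """Goodness of fit of each damage-corrected model to observed counts.

    For each mode, computes the pooled Pearson distance between observed
    per-codon nonsynonymous counts and the corrected expectation; lower is
    better. ``rand`` is a uniform-over-codons baseline.
    """
    index = codon_table.index
    if isinstance(observed_counts, Mapping):
        obs = np.zeros(len(index))
        for codon, cnt in observed_counts.items():
            obs[codon - 1] = cnt
    else:
        obs = np.asarray(observed_counts, dtype=float)
    if obs.sum() <= 0:
        raise ValueError("no observed mutations")
    rows = []
    mode_props: dict[str, np.ndarray] = {}
    for mode in modes:
        mode_props[mode] = corrected_codon_profile(
            codon_table, damage, mode
        ).to_numpy()
    if include_random_baseline:
        mode_props["rand"] = np.full(len(index), 1.0 / len(index))
    for mode, prop in mode_props.items():
        keep = prop > 0
        o, e = obs[keep], prop[keep] / prop[keep].sum()
        o_p, e_p, groups = pool_small_expectations(o, e)
        rows.append(
            {
                "mode": mode,
                "statistic": pearson_statistic(o_p, e_p),
                "n_channels": len(groups),
            }
        )
    return pd.DataFrame(rows).set_index("mode")


# ---------------------------------------------------------------------------
# dN/dS and driver fractions
# ---------------------------------------------------------------------------

@dataclass
class DnDsResult:
    """dN/dS for one mutation class against the mutability background.

    omega = (N_obs / S_obs) / (N_exp / S_exp), where the expected ratio
    comes from the background model's class mass relative to its synonymous
    mass. The 95% CI uses the log-ratio normal approximation on two Poisson
    counts: Var(log omega) ~ 1/N + 1/S.
    """

    omega: float
    ci_low: float
    ci_high: float
    mutation_class: str
    n_obs_nonsyn: int
    n_obs_syn: int
    expected_ratio: float
    unbounded_ci: bool = False

    def __post_init__(self):
        if not self.unbounded_ci:
            assert self.ci_low <= self.omega <= self.ci_high


def expected_class_ratio(
    profile: MutabilityProfile, gene: GeneModel, mutation_class: str
) -> float:
    """Model-expected (class mass) / (synonymous mass) ratio."""
    ctab_cols = {"truncating": "p_truncating", "non-truncating": "p_missense"}
    if mutation_class not in ctab_cols:
        raise ValueError(f"unknown class {mutation_class!r}")
    from .mutability import codon_profile  # local to avoid cycle at import

    ctab = codon_profile(profile, gene)
    syn = ctab["p_syn"].sum()
    cls_mass = ctab[ctab_cols[mutation_class]].sum()
    if mutation_class == "truncating" and profile.p_indel_total > 0:
        cls_mass += profile.p_indel_total
    if syn <= 0:
        raise ValueError("profile has zero synonymous mass")
    if cls_mass <= 0:
        raise ValueError(f"profile has zero {mutation_class} mass")
    return cls_mass / syn


def estimate_dnds(
    mutations: Iterable,
    profile: MutabilityProfile,
    gene: GeneModel,
    mutation_class: str = "non-truncating",
    z: float = 1.959963984540054,
) -> DnDsResult:
    """Estimate dN/dS for truncating or non-truncating mutations.

    Truncating = nonsense + frameshift (+ splice when annotated as such is
    excluded — panel annotations vary and carry no model mass); when the
    profile has no indel mass the frameshift observations are dropped and
    the ratio is computed on nonsense alone, with a warning.
    """
    want = set(
        TRUNCATING_CLASSES if mutation_class == "truncating"
        else ("missense",)
    )
    if mutation_class == "truncating" and profile.p_indel_total == 0:
        want = {"nonsense"}
    n_obs = s_obs = 0
    dropped_fs = 0
    for m in mutations:
        if m.gene != gene.symbol:
            continue
        if m.variant_class == "synonymous":
            s_obs += 1
        elif m.variant_class in want:
            n_obs += 1
        elif (
            mutation_class == "truncating"
            and m.variant_class == "frameshift"
        ):
            dropped_fs += 1
    if dropped_fs:
        warnings.warn(
            f"profile carries no indel mass; {dropped_fs} frameshift "
            "records dropped — truncating dN/dS is nonsense-only",
            stacklevel=2,
        )
    exp_ratio = expected_class_ratio(profile, gene, mutation_class)
    if s_obs == 0:
        return DnDsResult(
            omega=math.inf if n_obs else math.nan,
            ci_low=0.0,
            ci_high=math.inf,
            mutation_class=mutation_class,
            n_obs_nonsyn=n_obs,
            n_obs_syn=0,
            expected_ratio=exp_ratio,
            unbounded_ci=True,
        )
    omega = (n_obs / s_obs) / exp_ratio
    if n_obs == 0:
        return DnDsResult(
            omega=0.0, ci_low=0.0, ci_high=math.inf,
            mutation_class=mutation_class, n_obs_nonsyn=0, n_obs_syn=s_obs,
            expected_ratio=exp_ratio, unbounded_ci=True,
        )
    se = math.sqrt(1.0 / n_obs + 1.0 / s_obs)
    return DnDsResult(
        omega=omega,
        ci_low=omega * math.exp(-z * se),
        ci_high=omega * math.exp(z * se),
        mutation_class=mutation_class,
        n_obs_nonsyn=n_obs,
        n_obs_syn=s_obs,
        expected_ratio=exp_ratio,
    )


def driver_fraction(omega: float) -> float:
    """Fraction of observed mutations attributable to selection.

    Under dN/dS = omega, the neutral expectation contributes 1/omega of the
    observed nonsynonymous burden, so the excess (driver) fraction is
    (omega - 1) / omega, floored at 0.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    return max(0.0, (omega - 1.0) / omega)
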