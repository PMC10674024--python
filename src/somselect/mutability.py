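"""Trinucleotide-signature background mutability model for a coding sequence.

Given a 96-channel single-base-substitution spectrum (pyrimidine-centered,
COSMIC channel ordering) and a gene's coding sequence with one flanking base
on each side, this module predicts where mutations should fall *in the
absence of selection*: a probability for every (site, alt base) pair,
conditional on one substitution occurring somewhere in the gene. Aggregating
those probabilities by codon and by functional consequence (synonymous /
missense / truncating) gives the neutral expectation against which observed
hotspot profiles, substitution spectra and synonymous-site patterns are
tested.

The spectrum is taken as a single premixed 96-channel table (e.g. a
signature mixture already weighted for the tumor type); no signature
refitting is done here.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Observed-spectrum substitution classes, pyrimidine-centered.
SIX_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def cosmic_channels() -> list[str]:
    """The 96 SBS channels in COSMIC order, e.g. ``A[C>A]A`` ... ``T[T>G]T``."""
    channels = []
    for ref, alts in (("C", "AGT"), ("T", "ACG")):
        for alt in alts:
            for five in BASES:
                for three in BASES:
                    channels.append(f"{five}[{ref}>{alt}]{three}")
    return channels


CHANNELS_96 = cosmic_channels()
_CHANNEL_IDX = {c: i for i, c in enumerate(CHANNELS_96)}


def fold_channel(five: str, ref: str, alt: str, three: str) -> str:
    """Map any stranded substitution to its pyrimidine-centered channel."""
    if ref in "CT":
        return f"{five}[{ref}>{alt}]{three}"
    return (
        f"{revcomp(three)}[{revcomp(ref)}>{revcomp(alt)}]{revcomp(five)}"
    )


@dataclass
class TrinucleotideSpectrum:
    """A 96-channel relative substitution-frequency table.

    ``indel_rates`` optionally carries the fraction of total mutation events
    that are 1-bp homopolymer insertions/deletions (keys ``ins1``/``del1``);
    the SBS channels always sum to 1 among substitutions.
    """

    freqs: np.ndarray  # length 96, COSMIC order
    name: str = "spectrum"
    indel_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (96,):
            raise ValueError("spectrum must have exactly 96 channels")
        if np.any(self.freqs < 0) or np.any(~np.isfinite(self.freqs)):
            raise ValueError("channel frequencies must be finite and >= 0")
        total = self.freqs.sum()
        if total <= 0:
            raise ValueError("spectrum has zero total mass")
        self.freqs = self.freqs / total
        for key, rate in self.indel_rates.items():
            if key not in ("ins1", "del1") or not 0 <= rate < 1:
                raise ValueError(f"bad indel rate {key}={rate}")

    def __getitem__(self, channel: str) -> float:
        return float(self.freqs[_CHANNEL_IDX[channel]])

    @property
    def indel_fraction(self) -> float:
        return sum(self.indel_rates.values())

    @classmethod
    def uniform(cls, name: str = "uniform") -> "TrinucleotideSpectrum":
        return cls(np.ones(96), name=name)

    @classmethod
    def single_channel(cls, channel: str) -> "TrinucleotideSpectrum":
        freqs = np.zeros(96)
        freqs[_CHANNEL_IDX[channel]] = 1.0
        return cls(freqs, name=f"single:{channel}")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None
                 ) -> "TrinucleotideSpectrum":
        """Read a TSV with columns (context, frequency); context ``A[C>T]G``."""
        df = pd.read_csv(path, sep="\t")
        ctx_col, freq_col = df.columns[:2]
        freqs = np.zeros(96)
        for _, row in df.iterrows():
            freqs[_CHANNEL_IDX[str(row[ctx_col]).strip()]] = float(row[freq_col])
        return cls(freqs, name=name or Path(path).stem)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"context": CHANNELS_96, "frequency": self.freqs}).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A coding sequence with single-base flanks and its codon bookkeeping.

    ``protein_length`` counts amino-acid codons; a terminal stop codon, if
    present in the supplied CDS, is retained in ``cds`` but excluded from
    the mutability model (stop-gain at the natural stop is meaningless).
    """

    symbol: str
    cds: str
    flank5: str
    flank3: str
    protein: str = field(init=False)
    protein_length: int = field(init=False)

    def __post_init__(self):
        self.protein = str(Seq(self.cds).translate())
        ncod = len(self.cds) // 3
        self.protein_length = ncod - 1 if self.protein.endswith("*") else ncod

    @property
    def coding_length(self) -> int:
        """Number of modeled CDS sites (terminal stop excluded)."""
        return 3 * self.protein_length

    def codon_of_site(self, site: int) -> tuple[int, int]:
        """0-based CDS site -> (1-based codon index, position in codon)."""
        return site // 3 + 1, site % 3

    def codon(self, codon_index: int) -> str:
        """1-based codon index -> codon string."""
        i = (codon_index - 1) * 3
        return self.cds[i:i + 3]

    def context(self, site: int) -> tuple[str, str, str]:
        """(5' base, ref, 3' base) for a 0-based CDS site, using flanks."""
        seq = self.flank5 + self.cds + self.flank3
        return seq[site], seq[site + 1], seq[site + 2]


def build_gene_model(
    cds: str, symbol: str, flank5: str = "", flank3: str = ""
) -> GeneModel:
    """Validate and build a GeneModel from a coding-strand CDS plus flanks.

    Rejects sequences with internal stop codons; if the reverse complement
    translates cleanly the error advises a strand check. Flanking bases are
    required so terminal sites get real trinucleotide contexts — the model
    refuses to silently wrap or pad.
    """
    cds = cds.upper().strip()
    flank5, flank3 = flank5.upper().strip(), flank3.upper().strip()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    for nm, s, want in (("cds", cds, None), ("flank5", flank5, 1),
                        ("flank3", flank3, 1)):
        if any(b not in BASES for b in s):
            raise ValueError(f"{nm} contains non-ACGT (ambiguous?) bases")
        if want is not None and len(s) != want:
            raise ValueError(f"{nm} must be exactly one base, got {s!r}")
    protein = str(Seq(cds).translate())
    internal = protein[:-1] if protein.endswith("*") else protein
    if "*" in internal:
        rc_protein = str(Seq(revcomp(cds)).translate())
        rc_internal = (
            rc_protein[:-1] if rc_protein.endswith("*") else rc_protein
        )
        if "*" not in rc_internal:
            raise ValueError(
                "internal stop codons found, but the reverse complement "
                "translates cleanly — check the strand of the input CDS"
            )
        raise ValueError("CDS contains internal stop codon(s)")
    return GeneModel(symbol=symbol, cds=cds, flank5=flank5, flank3=flank3)


_CONSEQUENCE_CACHE: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def substitution_consequences(gene: GeneModel) -> tuple[np.ndarray, np.ndarray]:
    """Classify every (site, alt) single-base change in the modeled CDS.

    Returns ``(classes, aa_alts)``, each of shape (coding_length, 4) over
    alt bases ACGT: classes are ``"syn" | "mis" | "non" | ""`` (empty for
    alt == ref), aa_alts the resulting residue one-letter codes.
    """
    cached = _CONSEQUENCE_CACHE.get(gene.cds)
    if cached is not None:
        return cached
    L = gene.coding_length
    classes = np.full((L, 4), "", dtype="U3")
    aa_alts = np.full((L, 4), "", dtype="U1")
    for site in range(L):
        cidx, within = gene.codon_of_site(site)
        codon = gene.codon(cidx)
        aa_ref = gene.protein[cidx - 1]
        for ai, alt in enumerate(BASES):
            if alt == codon[within]:
                continue
            mutated = codon[:within] + alt + codon[within + 1:]
            aa_new = str(Seq(mutated).translate())
            aa_alts[site, ai] = aa_new
            if aa_new == aa_ref:
                classes[site, ai] = "syn"
            elif aa_new == "*":
                classes[site, ai] = "non"
            else:
                classes[site, ai] = "mis"
    classes.setflags(write=False)
    aa_alts.setflags(write=False)
    if len(_CONSEQUENCE_CACHE) > 32:
        _CONSEQUENCE_CACHE.clear()
    _CONSEQUENCE_CACHE[gene.cds] = (classes, aa_alts)
    return classes, aa_alts


# ---------------------------------------------------------------------------
# Mutability profile
# ---------------------------------------------------------------------------

@dataclass
class MutabilityProfile:
    """Per-(site, alt) mutation probabilities for one gene under one spectrum.

    ``p_site_alt[site, j]`` is the probability that, given a single
    substitution occurs in the gene, it hits CDS ``site`` producing alt base
    ``ACGT[j]``. Substitution probabilities sum to ``1 - p_indel_total``;
    the remaining mass sits on 1-bp homopolymer indels at qualifying runs.
    """

    gene: str
    spectrum: str
    p_site_alt: np.ndarray  # (coding_length, 4)
    indel_sites: pd.DataFrame | None = None  # columns: start, length, p_ins, p_del
    p_indel_total: float = 0.0

    def total_mass(self) -> float:
        return float(self.p_site_alt.sum()) + self.p_indel_total

    def site_totals(self) -> np.ndarray:
        return self.p_site_alt.sum(axis=1)


def homopolymer_runs(gene: GeneModel, min_run: int = 3) -> list[tuple[int, int, str]]:
    """Runs of identical bases with length >= min_run; (start, length, base)."""
    runs, cds = [], gene.cds[: gene.coding_length]
    i = 0
    while i < len(cds):
        j = i
        while j < len(cds) and cds[j] == cds[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j - i, cds[i]))
        i = j
    return runs


def site_mutability(
    gene: GeneModel,
    spectrum: TrinucleotideSpectrum,
    min_homopolymer_run: int = 3,
) -> MutabilityProfile:
    """Build the per-(site, alt) background mutability profile.

    Each coding-strand site's trinucleotide context is mapped to its
    pyrimidine-centered channel (reverse-complementing purine-centered
    sites); the probability of each (site, alt) is proportional to the
    matching channel frequency, normalized over the modeled CDS. When the
    spectrum carries indel rates, that fraction of total mass is spread
    over 1-bp homopolymer insertion/deletion events, weighted by run length.
    """
    L = gene.coding_length
    weights = np.zeros((L, 4))
    for site in range(L):
        five, ref, three = gene.context(site)
        for ai, alt in enumerate(BASES):
            if alt == ref:
                continue
            weights[site, ai] = spectrum[fold_channel(five, ref, alt, three)]
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            "spectrum assigns zero mass to every context in this gene"
        )
    sbs_mass = 1.0 - spectrum.indel_fraction
    p = weights / total * sbs_mass

    indel_df, p_indel = None, 0.0
    if spectrum.indel_fraction > 0:
        runs = homopolymer_runs(gene, min_homopolymer_run)
        if runs:
            lens = np.array([r[1] for r in runs], dtype=float)
            w = lens / lens.sum()
            ins = spectrum.indel_rates.get("ins1", 0.0)
            dele = spectrum.indel_rates.get("del1", 0.0)
            indel_df = pd.DataFrame(
                {
                    "start": [r[0] for r in runs],
                    "length": [r[1] for r in runs],
                    "base": [r[2] for r in runs],
                    "p_ins": w * ins,
                    "p_del": w * dele,
                }
            )
            p_indel = ins + dele
        else:
            # no qualifying runs: fold indel mass back onto substitutions
            p = weights / total
    return MutabilityProfile(
        gene=gene.symbol,
        spectrum=spectrum.name,
        p_site_alt=p,
        indel_sites=indel_df,
        p_indel_total=p_indel,
    )


def codon_profile(profile: MutabilityProfile, gene: GeneModel) -> pd.DataFrame:
    """Aggregate a profile to per-codon (p_syn, p_missense, p_truncating).

    Truncating mass is stop-gain (nonsense) substitutions; when the profile
    carries indel mass, the per-gene frameshift probability is reported in
    the frame ``attrs`` rather than per codon. Aggregates conserve the
    substitution mass exactly.
    """
    classes, _ = substitution_consequences(gene)
    n = gene.protein_length
    out = pd.DataFrame(
        0.0,
        index=pd.RangeIndex(1, n + 1, name="codon"),
        columns=["p_syn", "p_missense", "p_truncating"],
    )
    col = {"syn": "p_syn", "mis": "p_missense", "non": "p_truncating"}
    for site in range(gene.coding_length):
        cidx, _ = gene.codon_of_site(site)
        for ai in range(4):
            cls = classes[site, ai]
            if cls:
                out.loc[cidx, col[cls]] += profile.p_site_alt[site, ai]
    out["p_total"] = out.sum(axis=1)
    out.attrs["p_frameshift_indel"] = profile.p_indel_total
    out.attrs["gene"] = gene.symbol
    return out


def rank_predicted_hotspots(
    codon_table: pd.DataFrame, k: int = 5, mode: str = "nonsyn"
) -> pd.DataFrame:
    """Top-k predicted hotspot codons, frequencies relative to rank 1.

    ``mode="nonsyn"`` ranks on missense + truncating mass; ``"all"`` on the
    codon's total substitution mass. Ties break to the lower codon index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode == "nonsyn":
        score = codon_table["p_missense"] + codon_table["p_truncating"]
    elif mode == "all":
        score = codon_table["p_total"]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    order = sorted(score.index, key=lambda c: (-score[c], c))[:k]
    top = score.loc[order]
    rel = top / top.iloc[0] if top.iloc[0] > 0 else top
    return pd.DataFrame(
        {"codon": order, "predicted": top.values, "relative": rel.values}
    ).set_index(pd.RangeIndex(1, len(order) + 1, name="rank"))


# ---------------------------------------------------------------------------
# Observed spectra and spectrum tests
# ---------------------------------------------------------------------------

def observed_spectrum(mutations: Iterable, gene_symbol: str | None = None
                      ) -> pd.Series:
    """Tally substitutions into the 6 pyrimidine-centered classes.

    Purine-reference records are folded by complement (G>A counts as C>T).
    Insertions/deletions are tallied separately (``ins``/``del``); records
    that are neither single-base substitutions nor simple indels are counted
    under ``skipped``.
    """
    counts = {c: 0 for c in SIX_CLASSES}
    counts.update({"ins": 0, "del": 0, "skipped": 0})
    n_skipped = 0
    for m in mutations:
        if gene_symbol is not None and m.gene != gene_symbol:
            continue
        ref, alt = m.ref.upper(), m.alt.upper()
        if len(ref) == 1 and len(alt) == 1 and ref in BASES and alt in BASES:
            if ref in "AG":
                ref, alt = revcomp(ref), revcomp(alt)
            counts[f"{ref}>{alt}"] += 1
        elif ref in ("", "-") and len(alt) >= 1:
            counts["ins"] += 1
        elif alt in ("", "-") and len(ref) >= 1:
            counts["del"] += 1
        elif len(alt) > len(ref):
            counts["ins"] += 1
        elif len(ref) > len(alt):
            counts["del"] += 1
        else:
            counts["skipped"] += 1
            n_skipped += 1
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-SNV/non-indel records",
                      stacklevel=2)
    return pd.Series(counts)


def profile_six_class_expectation(
    profile: MutabilityProfile, gene: GeneModel
) -> pd.Series:
    """Expected 6-class substitution proportions under a mutability profile."""
    out = {c: 0.0 for c in SIX_CLASSES}
    for site in range(gene.coding_length):
        _, ref, _ = gene.context(site)
        for ai, alt in enumerate(BASES):
            if alt == ref:
                continue
            r, a = (ref, alt) if ref in "CT" else (revcomp(ref), revcomp(alt))
            out[f"{r}>{a}"] += profile.p_site_alt[site, ai]
    s = pd.Series(out)
    return s / s.sum()


def pool_small_expectations(
    observed: np.ndarray, expected_prop: np.ndarray, min_expected: float = 5.0
) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """Merge channels whose expected count falls below ``min_expected``.

    All undersized channels are merged into a single pooled channel; if the
    pool itself is still undersized it is merged with the smallest adequate
    channel. Returns (pooled observed, pooled expected proportions, groups).
    """
    n_total = observed.sum()
    exp_counts = n_total * expected_prop
    small = np.where(exp_counts < min_expected)[0]
    big = np.where(exp_counts >= min_expected)[0]
    groups = [[int(i)] for i in big]
    if len(small):
        pool = [int(i) for i in small]
        if exp_counts[small].sum() < min_expected and groups:
            smallest_big = min(groups, key=lambda g: exp_counts[g[0]])
            smallest_big.extend(pool)
        else:
            groups.append(pool)
    obs_p = np.array([observed[g].sum() for g in groups], dtype=float)
    exp_p = np.array([expected_prop[g].sum() for g in groups], dtype=float)
    return obs_p, exp_p, groups


def pearson_statistic(observed: np.ndarray, expected_prop: np.ndarray) -> float:
    """Plain Pearson goodness-of-fit statistic against given proportions."""
    n = observed.sum()
    exp = n * expected_prop
    mask = exp > 0
    return float(np.sum((observed[mask] - exp[mask]) ** 2 / exp[mask]))


@dataclass
class SpectrumTestResult:
    """Result of a Monte-Carlo Pearson goodness-of-fit comparison."""

    statistic: float
    p_value: float
    n_mc: int
    n_channels: int
    pooled_groups: list[list[int]]
    method: str = (
        "Pearson statistic; multinomial Monte-Carlo p-value; "
        "channels with expected count < 5 pooled"
    )

    def __post_init__(self):
        assert 0.0 <= self.p_value <= 1.0


def spectrum_compare(
    observed: Mapping[str, int] | Sequence[float] | np.ndarray,
    expected: Mapping[str, float] | Sequence[float] | np.ndarray,
    n_mc: int = 9999,
    seed: int | None = 0,
) -> SpectrumTestResult:
    """Test observed substitution counts against expected proportions.

    The Pearson statistic is computed on pooled channels and referred to a
    multinomial Monte-Carlo null resampled under the expected proportions
    (in place of the asymptotic chi-square reference, which is unreliable
    for sparse spectra). p-values are add-one corrected.
    """
    if n_mc < 999:
        raise ValueError("n_mc must be >= 999")
    if isinstance(observed, Mapping):
        keys = list(observed)
        obs = np.array([observed[k] for k in keys], dtype=float)
        exp = np.array(
            [expected[k] for k in keys]
            if isinstance(expected, Mapping)
            else expected,
            dtype=float,
        )
    else:
        obs = np.asarray(observed, dtype=float)
        exp = np.asarray(expected, dtype=float)
    n_total = int(obs.sum())
    if n_total == 0:
        raise ValueError("no observed substitutions to test")
    if exp.sum() <= 0:
        raise ValueError("expected proportions sum to zero")
    exp = exp / exp.sum()
    obs_p, exp_p, groups = pool_small_expectations(obs, exp)
    if np.any(exp_p <= 0):
        raise ValueError("expected proportions must be positive after pooling")
    stat = pearson_statistic(obs_p, exp_p)
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n_total, exp_p, size=n_mc).astype(float)
    exp_counts = n_total * exp_p
    sim_stats = ((sims - exp_counts) ** 2 / exp_counts).sum(axis=1)
    p = (np.sum(sim_stats >= stat - 1e-12) + 1) / (n_mc + 1)
    return SpectrumTestResult(
        statistic=stat,
        p_value=float(p),
        n_mc=n_mc,
        n_channels=len(groups),
        pooled_groups=groups,
    )


def synonymous_deviation_test(
    observed_syn: Mapping[int, int] | np.ndarray,
    profile: MutabilityProfile,
    gene: GeneModel,
    n_sims: int = 999,
    seed: int | None = 0,
) -> tuple[float, np.ndarray, float]:
    """Monte-Carlo deviation test on the synonymous-site mutation pattern.

    Synonymous changes do not alter the protein, so their placement should
    follow the background mutability alone; an extreme deviation flags
    DNA-level mutational processes the signature model misses. Simulates
    ``n_sims`` synonymous count vectors (multinomial over the profile's
    per-codon synonymous mass, same total as observed); the metric is the
    Pearson distance to expectation, unpooled — the Monte-Carlo reference
    distribution is valid for arbitrarily small expected counts, which is
    the point of replacing the asymptotic chi-square here. Returns
    (p_value, replicate metrics, observed metric); p is add-one corrected.
    """
    if n_sims < 999:
        raise ValueError("n_sims must be >= 999")
    ctab = codon_profile(profile, gene)
    syn_mass = ctab["p_syn"].to_numpy()
    if syn_mass.sum() <= 0:
        raise ValueError("profile has zero synonymous mass")
    exp_prop = syn_mass / syn_mass.sum()
    if isinstance(observed_syn, Mapping):
        obs = np.zeros(gene.protein_length)
        for codon, cnt in observed_syn.items():
            obs[codon - 1] = cnt
    else:
        obs = np.asarray(observed_syn, dtype=float)
    n_total = int(obs.sum())
    if n_total == 0:
        raise ValueError("no observed synonymous mutations")
    keep = exp_prop > 0
    dropped = int(obs[~keep].sum())
    if dropped:
        warnings.warn(
            f"{dropped} synonymous events at codons with zero model mass "
            "excluded from the deviation metric",
            stacklevel=2,
        )
    obs_k, exp_k = obs[keep], exp_prop[keep] / exp_prop[keep].sum()
    exp_counts = n_total * exp_k
    metric = float(np.sum((obs_k - exp_counts) ** 2 / exp_counts))
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n_total, exp_k, size=n_sims).astype(float)
    sim_metrics = ((sims - exp_counts) ** 2 / exp_counts).sum(axis=1)
    p = (np.sum(sim_metrics >= metric - 1e-12) + 1) / (n_sims + 1)
    return float(p), sim_metrics, float(metric)
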