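"""Synthetic tumor cohorts with known ground truth.

Generates cohorts that emulate the structure of large colorectal-cancer
panel datasets: a subtype mixture (MT-L / MT-H / MSS-htmb), subtype-specific
TMB distributions and trinucleotide spectra, signature-driven placement of
substitutions and simple homopolymer indels on a coding sequence, codon-level
positive selection optionally linked to functional damage, depletion of
mutations at an interface residue set, pairwise co-occurrence structure among
driver genes (multivariate Bernoulli matched to marginals and log odds
ratios by iterative proportional fitting), and clonal/subclonal allele
fractions. Every generated cohort carries its ground truth, so each
estimator in the package can be checked for parameter recovery.

The default parameters are the study conditions of the cohort being
emulated: subtype proportions 94.6% / 4.7% / 0.7%, focal-gene mutation
frequencies 3.9% / 18.1% / 44.0% per subtype, selection strengths implying
~94% (non-truncating) and ~95% (truncating) driver fractions, and a 3.8-fold
interface depletion.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import MutationRecord, SampleRecord
from .functional import FunctionalScoreTable
from .mutability import (
    BASES,
    CHANNELS_96,
    GeneModel,
    TrinucleotideSpectrum,
    build_gene_model,
    site_mutability,
    substitution_consequences,
)
from .spatial import ResidueSet

_STOP_CODONS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Synthetic reference objects
# ---------------------------------------------------------------------------

def synthetic_gene(
    n_codons: int = 403,
    seed: int = 20402,
    symbol: str = "SYNGENE",
    arg_fraction: float = 0.08,
) -> GeneModel:
    """A synthetic tumor-suppressor-like coding sequence (stand-in gene).

    Random codons with an elevated share of CpG-bearing arginine codons
    (CGA/CGC/CGG), so that deamination-style spectra concentrated on
    N[C>T]G contexts produce arginine-codon hotspots — the mechanism behind
    recurrent R->Q/R->* hotspots in real tumor suppressors. Internal stop
    codons are excluded; a terminal stop is appended. This is a synthetic
    stand-in, not any real gene's sequence.
    """
    rng = np.random.default_rng(seed)
    all_codons = [
        a + b + c
        for a in BASES for b in BASES for c in BASES
        if a + b + c not in _STOP_CODONS
    ]
    arg_codons = ["CGA", "CGC", "CGG"]
    codons = []
    for _ in range(n_codons):
        if rng.random() < arg_fraction:
            codons.append(arg_codons[rng.integers(len(arg_codons))])
        else:
            codons.append(all_codons[rng.integers(len(all_codons))])
    codons[0] = "ATG"
    cds = "".join(codons) + "TGA"
    flank5 = BASES[rng.integers(4)]
    flank3 = BASES[rng.integers(4)]
    return build_gene_model(cds, symbol, flank5=flank5, flank3=flank3)


def crc_like_spectrum(subtype: str = "MT-L") -> TrinucleotideSpectrum:
    """A premixed 96-channel spectrum emulating colorectal mutagenesis.

    MT-L: dominated by clock-like CpG deamination (C>T at N[C>T]G, ~55% of
    substitution mass) over a flat residual, with a small homopolymer-indel
    component where insertions outnumber deletions. MT-H: mismatch-repair
    deficient — broader C>T plus T>C mass and a large deletion-dominated
    indel component. MSS-htmb: proofreading-deficient-like, C>A at TpCpT
    contexts. Synthetic mixtures, not fitted signature catalogs.
    """
    freqs = np.full(96, 1.0)
    idx = {c: i for i, c in enumerate(CHANNELS_96)}
    if subtype == "MT-L":
        for five in BASES:
            freqs[idx[f"{five}[C>T]G"]] = 30.0
        indels = {"ins1": 0.04, "del1": 0.02}
    elif subtype == "MT-H":
        for five in BASES:
            freqs[idx[f"{five}[C>T]G"]] = 12.0
            for three in BASES:
                freqs[idx[f"{five}[T>C]{three}"]] += 2.0
        indels = {"ins1": 0.04, "del1": 0.20}
    elif subtype == "MSS-htmb":
        freqs[idx["T[C>A]T"]] = 40.0
        freqs[idx["T[C>T]G"]] = 20.0
        indels = {}
    else:
        raise ValueError(f"unknown subtype {subtype!r}")
    return TrinucleotideSpectrum(freqs, name=f"crc-like:{subtype}",
                                 indel_rates=indels)


def synthetic_score_table(
    gene: GeneModel,
    seed: int = 7,
    coverage: float = 0.92,
    damaging_prob_catalytic: float = 0.65,
    damaging_prob_other: float = 0.35,
    catalytic_end: int | None = None,
) -> FunctionalScoreTable:
    """Synthetic per-substitution activity/abundance scores (stand-in table).

    Emulates a deep-mutational-scanning score table: every accessible
    missense change gets activity (lpa) and abundance scores on a wild-type
    =~1 scale; damaging changes score low on one or both. Changes in the
    N-terminal catalytic-domain-like region are damaging more often. A
    (1 - coverage) fraction of substitutions is left unscored (NaN).
    """
    rng = np.random.default_rng(seed)
    cat_end = catalytic_end or gene.protein_length // 2
    classes, aa_alts = substitution_consequences(gene)
    rows, seen = [], set()
    for site in range(gene.coding_length):
        cidx = site // 3 + 1
        for ai in range(4):
            if classes[site, ai] != "mis":
                continue
            key = (cidx, aa_alts[site, ai])
            if key in seen:
                continue
            seen.add(key)
            if rng.random() > coverage:
                rows.append(
                    {"codon": key[0], "aa_alt": key[1],
                     "lpa_score": np.nan, "abundance_score": np.nan}
                )
                continue
            p_dam = (
                damaging_prob_catalytic if cidx <= cat_end
                else damaging_prob_other
            )
            damaging = rng.random() < p_dam
            if damaging:
                lpa = 0.5 * rng.beta(2, 5)  # activity strictly sub-cutoff
                ab = (
                    0.5 * rng.beta(2, 4) if rng.random() < 0.5
                    else 0.6 + 0.4 * rng.beta(8, 2)
                )
            else:
                lpa = 0.6 + 0.4 * rng.beta(4, 2)
                ab = 0.6 + 0.4 * rng.beta(4, 2)
            rows.append(
                {"codon": key[0], "aa_alt": key[1],
                 "lpa_score": float(lpa), "abundance_score": float(ab)}
            )
    return FunctionalScoreTable(scores=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Simulation configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """All knobs of the cohort generator; defaults are the study conditions."""

    n_tumors: int = 1000
    subtype_props: dict[str, float] = field(
        default_factory=lambda: {"MT-L": 0.946, "MT-H": 0.047,
                                 "MSS-htmb": 0.007}
    )
    #: lognormal (mu, sigma) of TMB per subtype, resampled into the
    #: subtype's TMB window [0,16) / [16,100] / (100, inf)
    tmb_lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "MT-L": (1.5, 0.6),
            "MT-H": (3.5, 0.4),
            "MSS-htmb": (5.0, 0.3),
        }
    )
    #: focal-gene mutation frequency per subtype
    gene_mut_freq: dict[str, float] = field(
        default_factory=lambda: {"MT-L": 0.039, "MT-H": 0.181,
                                 "MSS-htmb": 0.44}
    )
    #: dN/dS-style selection multipliers; defaults imply ~94% / 95%
    #: driver fractions
    truncating_omega: float = 20.0
    nontruncating_omega: float = 16.7
    #: when True, the non-truncating multiplier applies only to changes
    #: classified LoF by the damage table; WT-like changes stay neutral
    damage_linked: bool = True
    interface_residues: tuple[int, ...] = ()
    interface_depletion: float = 3.8
    #: driver-gene marginal mutation frequencies
    driver_marginals: dict[str, float] = field(
        default_factory=lambda: {
            "APC": 0.70, "TP53": 0.60, "KRAS": 0.45,
            "BRAF": 0.10, "PIK3CA": 0.20, "SMAD4": 0.12,
        }
    )
    #: pairwise log odds ratios between genes (driver or focal); unlisted
    #: pairs are independent
    pairwise_log_or: dict[tuple[str, str], float] = field(default_factory=dict)
    #: tumor purity; clonal AF ~ Beta(conc*m, conc*(1-m)) with m = purity/2
    purity: float = 0.6
    af_concentration: float = 30.0
    subclonal_fraction: float = 0.25
    subclonal_scale: float = 0.3
    fraction_ms_known: float = 0.3
    stage_props: tuple[float, float, float, float] = (0.2, 0.3, 0.3, 0.2)
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.subtype_props.values()) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if self.truncating_omega <= 0 or self.nontruncating_omega <= 0:
            raise ValueError("selection multipliers must be positive")
        if self.interface_depletion < 1:
            raise ValueError("depletion factor must be >= 1")


@dataclass
class SimTruth:
    """Ground truth serialized alongside a simulated cohort."""

    subtype: dict[str, str]
    mutation_truth: pd.DataFrame  # sample_id, gene, class, damaging, clonal
    truncating_omega: float
    nontruncating_omega: float
    interface_depletion: float
    pairwise_log_or: dict[tuple[str, str], float]
    seed: int


# ---------------------------------------------------------------------------
# Driver genotypes via iterative proportional fitting
# ---------------------------------------------------------------------------

def _pairwise_p11(mi: float, mj: float, log_or: float,
                  pair: tuple[str, str]) -> float:
    """P(both mutated) given two marginals and a log odds ratio."""
    lo, hi = max(0.0, mi + mj - 1.0), min(mi, mj)
    if log_or == 0.0:
        return mi * mj
    if not (0.0 < mi < 1.0 and 0.0 < mj < 1.0):
        raise ValueError(
            f"infeasible log-OR/marginals for pair {pair}: a degenerate "
            "marginal admits no association"
        )
    odds = np.exp(log_or)
    a = odds - 1.0
    b = -((odds - 1.0) * (mi + mj) + 1.0)
    c = odds * mi * mj
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError(f"infeasible log-OR/marginals for pair {pair}")
    p11 = (-b - np.sqrt(disc)) / (2 * a)
    if not (lo - 1e-9 <= p11 <= hi + 1e-9):
        raise ValueError(f"infeasible log-OR/marginals for pair {pair}")
    return float(np.clip(p11, lo, hi))


def joint_bernoulli(
    marginals: Mapping[str, float],
    pairwise_log_or: Mapping[tuple[str, str], float],
    tol: float = 1e-12,
    max_iter: int = 2000,
) -> tuple[list[str], np.ndarray]:
    """Joint distribution over binary genotypes matching marginals + log-ORs.

    Starts from the independence joint and iteratively rescales to match
    every constrained pairwise 2x2 table and every marginal (iterative
    proportional fitting over the full 2^k table).
    """
    genes = list(marginals)
    k = len(genes)
    if k > 16:
        raise ValueError("too many genes for an exact joint (2^k cells)")
    gidx = {g: i for i, g in enumerate(genes)}
    states = np.array(
        [[(s >> i) & 1 for i in range(k)] for s in range(2 ** k)], dtype=bool
    )
    m = np.array([marginals[g] for g in genes])
    joint = np.prod(np.where(states, m, 1 - m), axis=1)
    targets = {}
    for (g1, g2), lor in pairwise_log_or.items():
        p11 = _pairwise_p11(marginals[g1], marginals[g2], lor, (g1, g2))
        mi, mj = marginals[g1], marginals[g2]
        targets[(gidx[g1], gidx[g2])] = np.array(
            [[1 - mi - mj + p11, mj - p11], [mi - p11, p11]]
        )
    for _ in range(max_iter):
        delta = 0.0
        for (i, j), tab in targets.items():
            for si in (0, 1):
                for sj in (0, 1):
                    mask = (states[:, i] == si) & (states[:, j] == sj)
                    cur = joint[mask].sum()
                    if cur > 0:
                        factor = tab[si, sj] / cur
                        joint[mask] *= factor
                        delta = max(delta, abs(factor - 1.0))
        for i in range(k):
            mask = states[:, i]
            cur = joint[mask].sum()
            if 0 < cur < 1:
                joint[mask] *= m[i] / cur
                joint[~mask] *= (1 - m[i]) / (1 - cur)
                delta = max(delta, abs(m[i] / cur - 1.0))
        joint /= joint.sum()
        if delta < tol:
            break
    return genes, joint


# ---------------------------------------------------------------------------
# Gene-level mutation placement
# ---------------------------------------------------------------------------

def _draw_af(rng: np.random.Generator, cfg: SimConfig, clonal: bool) -> float:
    mean = cfg.purity / 2.0
    conc = cfg.af_concentration
    af = rng.beta(conc * mean, conc * (1 - mean))
    if not clonal:
        af *= cfg.subclonal_scale * (0.5 + rng.random())
    return float(np.clip(af, 1e-4, 1.0))


def simulate_gene_mutations(
    gene: GeneModel,
    spectrum: TrinucleotideSpectrum,
    n: int,
    config: SimConfig | None = None,
    damage: FunctionalScoreTable | None = None,
    interface: ResidueSet | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    sample_ids: Sequence[str] | None = None,
) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Place ``n`` mutation events on a gene under selection and depletion.

    Acceptance-resampling: each candidate event (site, alt) — or a 1-bp
    homopolymer indel when the spectrum carries indel mass — gets weight
    (background probability) x (class selection multiplier, optionally
    linked to functional damage) / (depletion factor when the codon lies in
    the interface). Weights are renormalized so the realized count is
    exactly ``n``. Returns the records plus a per-mutation truth table.
    """
    cfg = config or SimConfig()
    rng = rng or np.random.default_rng(seed)
    profile = site_mutability(gene, spectrum)
    classes, aa_alts = substitution_consequences(gene)
    iface = frozenset(interface.residues) if interface is not None else frozenset()

    events: list[tuple] = []  # (kind, site, alt_idx, codon, class, damaging)
    weights: list[float] = []
    from .config import default_config
    fcfg = default_config()
    for site in range(gene.coding_length):
        codon = site // 3 + 1
        for ai in range(4):
            cls = classes[site, ai]
            if not cls:
                continue
            p = profile.p_site_alt[site, ai]
            if p <= 0:
                continue
            damaging = cls == "non"
            if cls == "non":
                w = p * cfg.truncating_omega
            elif cls == "mis":
                if cfg.damage_linked and damage is not None:
                    lpa, ab = damage.lookup(codon, aa_alts[site, ai])
                    is_lof = (
                        lpa is not None and lpa < fcfg["lpa_cutoff"]
                    ) or (ab is not None and ab < fcfg["abundance_cutoff"])
                    damaging = bool(is_lof)
                    w = p * (cfg.nontruncating_omega if is_lof else 1.0)
                else:
                    damaging = True
                    w = p * cfg.nontruncating_omega
            else:  # synonymous: neutral by definition
                w = p
            if codon in iface and cls != "syn":
                w /= cfg.interface_depletion
            events.append(("snv", site, ai, codon, cls, damaging))
            weights.append(w)
    if profile.indel_sites is not None:
        for row in profile.indel_sites.itertuples():
            p_run = row.p_ins + row.p_del
            codon = row.start // 3 + 1
            w = p_run * cfg.truncating_omega
            if codon in iface:
                w /= cfg.interface_depletion
            events.append(("indel", row.start, -1, codon, "frameshift", True))
            weights.append(w)
    w = np.asarray(weights)
    if w.sum() <= 0:
        raise ValueError("all acceptance weights are zero")
    counts = rng.multinomial(n, w / w.sum())

    cls_name = {"syn": "synonymous", "mis": "missense", "non": "nonsense",
                "frameshift": "frameshift"}
    records, truth_rows = [], []
    k = 0
    for (kind, site, ai, codon, cls, damaging), cnt in zip(events, counts):
        for _ in range(cnt):
            sid = sample_ids[k] if sample_ids is not None else f"T{k:05d}"
            clonal = bool(rng.random() > cfg.subclonal_fraction)
            af = _draw_af(rng, cfg, clonal)
            if kind == "snv":
                ref = gene.cds[site]
                alt = BASES[ai]
                rec = MutationRecord(
                    sample_id=sid, gene=gene.symbol, chrom="CDS",
                    pos=site + 1, ref=ref, alt=alt,
                    variant_class=cls_name[cls], protein_pos=codon,
                    aa_ref=gene.protein[codon - 1],
                    aa_alt=aa_alts[site, ai] or gene.protein[codon - 1],
                    allele_fraction=af,
                )
            else:
                ref = gene.cds[site]
                rec = MutationRecord(
                    sample_id=sid, gene=gene.symbol, chrom="CDS",
                    pos=site + 1, ref=ref, alt="",
                    variant_class="frameshift", protein_pos=codon,
                    allele_fraction=af,
                )
            records.append(rec)
            truth_rows.append(
                {
                    "sample_id": sid, "gene": gene.symbol,
                    "variant_class": cls_name[cls], "codon": codon,
                    "damaging": damaging, "clonal": clonal,
                    "in_interface": codon in iface,
                }
            )
            k += 1
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "gene", "variant_class", "codon", "damaging",
                 "clonal", "in_interface"],
    )
    return records, truth


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------

_TMB_WINDOWS = {"MT-L": (0.0, 16.0), "MT-H": (16.0, 100.0),
                "MSS-htmb": (100.0, np.inf)}


def _draw_tmb(rng: np.random.Generator, cfg: SimConfig, subtype: str) -> float:
    mu, sigma = cfg.tmb_lognormal[subtype]
    lo, hi = _TMB_WINDOWS[subtype]
    for _ in range(1000):
        t = float(rng.lognormal(mu, sigma))
        if lo <= t < hi or (subtype == "MT-H" and t == hi):
            return t
    return float(np.clip(t, lo, min(hi, 1e4)))


def simulate_cohort(
    config: SimConfig | None = None,
    gene: GeneModel | None = None,
    spectra: Mapping[str, TrinucleotideSpectrum] | None = None,
    damage: FunctionalScoreTable | None = None,
    interface: ResidueSet | None = None,
) -> tuple[list[MutationRecord], list[SampleRecord], SimTruth]:
    """Simulate a full cohort; reproducible record-for-record from the seed."""
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gene = gene or synthetic_gene()
    spectra = spectra or {st: crc_like_spectrum(st) for st in cfg.subtype_props}
    if interface is None and cfg.interface_residues:
        interface = ResidueSet("interface",
                               frozenset(cfg.interface_residues))

    subtypes = list(cfg.subtype_props)
    props = np.array([cfg.subtype_props[s] for s in subtypes])
    draws = rng.choice(len(subtypes), size=cfg.n_tumors, p=props)

    focal = gene.symbol
    marginals = dict(cfg.driver_marginals)
    focal_in_joint = any(focal in pair for pair in cfg.pairwise_log_or)
    if focal_in_joint:
        marginals[focal] = float(
            sum(cfg.subtype_props[s] * cfg.gene_mut_freq[s] for s in subtypes)
        )
    genes_joint, joint = joint_bernoulli(marginals, cfg.pairwise_log_or)
    states = np.array(
        [[(s >> i) & 1 for i in range(len(genes_joint))]
         for s in range(2 ** len(genes_joint))],
        dtype=bool,
    )
    cells = rng.choice(len(joint), size=cfg.n_tumors, p=joint)

    samples: list[SampleRecord] = []
    mutations: list[MutationRecord] = []
    truth_frames: list[pd.DataFrame] = []
    subtype_truth: dict[str, str] = {}
    stages = ("I", "II", "III", "IV")

    carrier_ids: list[str] = []
    carrier_subtype: list[str] = []
    for t in range(cfg.n_tumors):
        sid = f"S{t:05d}"
        st = subtypes[draws[t]]
        subtype_truth[sid] = st
        tmb = _draw_tmb(rng, cfg, st)
        known = rng.random() < cfg.fraction_ms_known
        ms_known = (
            ("MSI-H" if st == "MT-H" else "MSS") if known else "unknown"
        )
        stage = stages[rng.choice(4, p=np.array(cfg.stage_props))]
        samples.append(
            SampleRecord(
                sample_id=sid, ms_status_known=ms_known, tmb=tmb,
                panel_id="sim", stage=stage,
            )
        )
        genotype = states[cells[t]]
        for gi, gname in enumerate(genes_joint):
            if gname == focal or not genotype[gi]:
                continue
            af = _draw_af(rng, cfg, clonal=True)
            mutations.append(
                MutationRecord(
                    sample_id=sid, gene=gname, variant_class="missense",
                    allele_fraction=af,
                )
            )
        if focal_in_joint:
            is_carrier = bool(genotype[genes_joint.index(focal)])
        else:
            is_carrier = rng.random() < cfg.gene_mut_freq[st]
        if is_carrier:
            carrier_ids.append(sid)
            carrier_subtype.append(st)

    # place focal-gene mutations carrier by carrier, per-subtype spectrum
    for st in subtypes:
        ids = [s for s, cs in zip(carrier_ids, carrier_subtype) if cs == st]
        if not ids:
            continue
        recs, truth = simulate_gene_mutations(
            gene, spectra[st], n=len(ids), config=cfg, damage=damage,
            interface=interface, rng=rng, sample_ids=ids,
        )
        mutations.extend(recs)
        if len(truth):
            truth = truth.assign(subtype=st)
            truth_frames.append(truth)

    mutation_truth = (
        pd.concat(truth_frames, ignore_index=True)
        if truth_frames
        else pd.DataFrame(
            columns=["sample_id", "gene", "variant_class", "codon",
                     "damaging", "clonal", "in_interface", "subtype"]
        )
    )
    truth = SimTruth(
        subtype=subtype_truth,
        mutation_truth=mutation_truth,
        truncating_omega=cfg.truncating_omega,
        nontruncating_omega=cfg.nontruncating_omega,
        interface_depletion=cfg.interface_depletion,
        pairwise_log_or=dict(cfg.pairwise_log_or),
        seed=cfg.seed,
    )
    return mutations, samples, truth
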