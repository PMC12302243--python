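"""Synthetic paired-timepoint repertoire and single-cell count generator.

The generator emulates the statistical structure that the depletion analysis
assumes, with full ground truth for recovery tests:

* Per donor and locus, a baseline (M00) repertoire with heavy-tailed
  (Zipf) clone abundances over a fixed lineage richness, synthetic V/J
  germline alleles and random junctions.
* IGH lineages carry a B-cell maturity class; somatic hypermutation is placed
  as lineage-trunk mutations on a synthetic 300-nt V region (Poisson mean per
  class) plus small per-sequence mutations, keeping within-lineage junction
  divergence far below the lineage-clustering threshold so clonotype truth is
  well defined.
* At follow-up (M06), anti-CD20 depletion removes B lineages and CD20dim /
  Vd2+ T clones.  OCR donors follow one of two B-cell scenarios: *residual*
  (few cells, only persistent memory lineages re-observed) or *reconstituted*
  (many fresh near-germline naive lineages, new sequences).  Control cohorts
  (HD, NAT) resample their baseline with mild lineage turnover for B cells
  and none for T cells.
* A toy single-cell count matrix with subset labels, timepoints and
  protein-positivity labels for marker-gating tests.

Identical config + seed yields byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._rng import derive_seed, rng_for
from .airr_io import Rearrangement, RepertoireSample, write_rearrangements
from .errors import ConfigError

_NTS = "ACGT"

RESIDUAL = "residual"
RECONSTITUTED = "reconstituted"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class GermlineConfig:
    """Synthetic germline allele set (a small stand-in reference)."""

    v_region_length: int = 300
    j_length: int = 48
    n_v_genes: dict = field(default_factory=lambda: {"IGH": 12, "TRB": 10, "TRD": 3})
    alleles_per_gene: int = 2
    n_j_genes: dict = field(default_factory=lambda: {"IGH": 6, "TRB": 8, "TRD": 4})
    junction_lengths: tuple = (30, 33, 36, 39, 42, 45, 48, 51, 54, 57)
    seed: int = 104729  # fixed: the reference is part of the scenario, not the draw


@dataclass
class ShmConfig:
    """Per-lineage mutation model by B-cell maturity class."""

    naive_mu: float = 0.5
    memory_mu: float = 20.0
    naive_fraction: float = 0.6
    extra_per_sequence: float = 0.7
    junction_variant_prob: float = 0.25
    variants_naive: float = 0.35   # Poisson mean of extra unique sequences per lineage
    variants_memory: float = 1.2


@dataclass
class BFollowupConfig:
    """Bimodal follow-up scenarios for anti-CD20 treated donors."""

    reconstituted_fraction: float = 0.5
    residual_m06_mean: float = 450.0
    reconstituted_m06_mean: float = 8350.0
    m06_sigma: float = 0.5
    persistence: float = 0.8           # memory lineages re-observed in residual donors
    naive_richness_fraction: float = 0.7  # new naive lineages per sequenced M06 cell
    residual_weight_share: float = 0.05   # M06 mass on surviving lineages (reconstituted)


@dataclass
class DepletionConfig:
    """Anti-CD20 depletion of T-cell clones and B lineages."""

    f_T: float = 1.0      # P(depleted | CD20dim TRB clone)
    f_B: float = 0.99     # P(depleted | baseline B lineage)
    f_vd2: float = 0.5    # P(depleted | Vd2+ TRD clone)
    cd20dim_marginal: float = 0.08   # CD20dim share of T cells (5-10% in blood)
    cd20dim_logit_slope: float = 1.5  # enrichment of CD20dim among expanded clones


@dataclass
class LocusDepth:
    """Per-locus repertoire depth: lineage richness and molecule counts."""

    richness: int
    baseline_mean: dict          # cohort -> mean molecules at M00 (and M06 for controls)
    sigma: float = 0.5


def _default_igh() -> LocusDepth:
    return LocusDepth(
        richness=800,
        baseline_mean={"HD": 25000.0, "NAT": 77601.0, "OCR": 53670.0},
        sigma=0.5,
    )


def _default_trb() -> LocusDepth:
    return LocusDepth(
        richness=1500,
        baseline_mean={"HD": 150000.0, "NAT": 150000.0, "OCR": 150000.0},
        sigma=0.3,
    )


def _default_trd() -> LocusDepth:
    return LocusDepth(
        richness=400,
        baseline_mean={"HD": 8000.0, "NAT": 8000.0, "OCR": 8000.0},
        sigma=0.4,
    )


@dataclass
class ScenarioConfig:
    """Full parameterization of a synthetic paired-timepoint cohort."""

    n_donors: dict = field(default_factory=lambda: {"HD": 11, "NAT": 14, "OCR": 35})
    loci: tuple = ("IGH", "TRB", "TRD")
    zipf_s: float = 1.1
    igh: LocusDepth = field(default_factory=_default_igh)
    trb: LocusDepth = field(default_factory=_default_trb)
    trd: LocusDepth = field(default_factory=_default_trd)
    shm: ShmConfig = field(default_factory=ShmConfig)
    b_followup: BFollowupConfig = field(default_factory=BFollowupConfig)
    depletion: DepletionConfig = field(default_factory=DepletionConfig)
    germline: GermlineConfig = field(default_factory=GermlineConfig)
    hd_nat_b_turnover: float = 0.15  # new IGH lineage mass at M06 in control cohorts
    vd2_fraction: float = 0.55       # TRD clones using the TRDV2 gene
    seed: int = 0

    def locus_depth(self, locus: str) -> LocusDepth:
        return {"IGH": self.igh, "TRB": self.trb, "TRD": self.trd}[locus]

    def validate(self) -> None:
        fractions = [
            self.b_followup.reconstituted_fraction,
            self.b_followup.persistence,
            self.b_followup.residual_weight_share,
            self.depletion.f_T,
            self.depletion.f_B,
            self.depletion.f_vd2,
            self.depletion.cd20dim_marginal,
            self.hd_nat_b_turnover,
            self.vd2_fraction,
            self.shm.naive_fraction,
        ]
        if any(not (0.0 <= f <= 1.0) for f in fractions):
            raise ConfigError("scenario fractions must lie in [0, 1]")
        if self.zipf_s <= 0:
            raise ConfigError("Zipf exponent must be > 0")
        for locus in self.loci:
            depth = self.locus_depth(locus)
            if depth.richness < 1:
                raise ConfigError(f"{locus}: richness must be >= 1")
            if any(m < 0 for m in depth.baseline_mean.values()):
                raise ConfigError(f"{locus}: negative baseline mean")
        if any(n < 0 for n in self.n_donors.values()):
            raise ConfigError("donor counts must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        data = dict(data)
        nested = {
            "igh": LocusDepth,
            "trb": LocusDepth,
            "trd": LocusDepth,
            "shm": ShmConfig,
            "b_followup": BFollowupConfig,
            "depletion": DepletionConfig,
            "germline": GermlineConfig,
        }
        for key, klass in nested.items():
            if key in data and isinstance(data[key], dict):
                data[key] = klass(**data[key])
        if "loci" in data:
            data["loci"] = tuple(data["loci"])
        if "germline" in data and isinstance(data["germline"], GermlineConfig):
            data["germline"].junction_lengths = tuple(data["germline"].junction_lengths)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# germline reference
# ---------------------------------------------------------------------------


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(_NTS[i] for i in rng.integers(0, 4, length))


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in positions:
        current = chars[pos]
        choices = [c for c in _NTS if c != current]
        chars[pos] = choices[rng.integers(0, 3)]
    return "".join(chars)


@dataclass
class GermlineSet:
    """Named V and J allele sequences per locus."""

    v_alleles: dict  # locus -> {allele name: sequence}
    j_alleles: dict
    junction_lengths: tuple


def build_germline(cfg: GermlineConfig) -> GermlineSet:
    """Deterministic synthetic allele set (not a real IMGT reference)."""
    rng = np.random.default_rng(cfg.seed)
    v_alleles: dict[str, dict[str, str]] = {}
    j_alleles: dict[str, dict[str, str]] = {}
    for locus in ("IGH", "TRB", "TRD"):
        prefix = {"IGH": "IGHV", "TRB": "TRBV", "TRD": "TRDV"}[locus]
        jprefix = {"IGH": "IGHJ", "TRB": "TRBJ", "TRD": "TRDJ"}[locus]
        v: dict[str, str] = {}
        for g in range(1, cfg.n_v_genes[locus] + 1):
            base = _random_nt(rng, cfg.v_region_length)
            for a in range(1, cfg.alleles_per_gene + 1):
                if a == 1:
                    v[f"{prefix}{g}*0{a}"] = base
                else:
                    pos = rng.choice(cfg.v_region_length, size=2, replace=False)
                    v[f"{prefix}{g}*0{a}"] = _mutate(base, pos, rng)
        j = {
            f"{jprefix}{g}*01": _random_nt(rng, cfg.j_length)
            for g in range(1, cfg.n_j_genes[locus] + 1)
        }
        v_alleles[locus] = v
        j_alleles[locus] = j
    return GermlineSet(
        v_alleles=v_alleles, j_alleles=j_alleles, junction_lengths=cfg.junction_lengths
    )


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _zipf_weights(richness: int, s: float) -> np.ndarray:
    w = np.arange(1, richness + 1, dtype=float) ** (-s)
    return w / w.sum()


def _lognormal_count(rng: np.random.Generator, mean: float, sigma: float) -> int:
    """Integer draw from a log-normal with the given arithmetic mean."""
    if mean <= 0:
        return 0
    mu = np.log(mean) - sigma**2 / 2.0
    return max(1, int(round(rng.lognormal(mu, sigma))))


def _cd20dim_probabilities(richness: int, marginal: float, slope: float) -> np.ndarray:
    """Logistic-in-log-rank CD20dim probabilities with a fixed marginal.

    Rank 1 is the most expanded clone; the logit decreases with log rank, and
    the intercept is solved so the mean probability equals ``marginal``.
    """
    if marginal <= 0.0:
        return np.zeros(richness)
    if marginal >= 1.0:
        return np.ones(richness)
    x = np.log(np.arange(1, richness + 1, dtype=float))
    z = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)

    def gap(a: float) -> float:
        return expit(a - slope * z).mean() - marginal

    a = brentq(gap, -40.0, 40.0)
    return expit(a - slope * z)


# ---------------------------------------------------------------------------
# B-cell (IGH) simulation
# ---------------------------------------------------------------------------


@dataclass
class _BLineage:
    lineage_id: str
    naive: bool
    v_call: str
    j_call: str
    junction: str
    trunk_v: str       # mutated V region shared by the lineage
    germline_v: str
    j_seq: str
    n_variants: int
    variants: Optional[list] = None  # [(v_region, junction)] built on demand

    def build_variants(self, rng: np.random.Generator, shm: ShmConfig) -> list:
        if self.variants is None:
            variants = [(self.trunk_v, self.junction)]
            for _ in range(self.n_variants - 1):
                n_extra = 1 + rng.poisson(shm.extra_per_sequence)
                pos = rng.choice(len(self.trunk_v), size=min(n_extra, 10), replace=False)
                v_region = _mutate(self.trunk_v, pos, rng)
                junction = self.junction
                if rng.random() < shm.junction_variant_prob:
                    jpos = np.array([rng.integers(0, len(junction))])
                    junction = _mutate(junction, jpos, rng)
                variants.append((v_region, junction))
            self.variants = variants
        return self.variants


def _make_b_lineage(
    lineage_id: str,
    naive: bool,
    germ: GermlineSet,
    shm: ShmConfig,
    rng: np.random.Generator,
) -> _BLineage:
    v_names = sorted(germ.v_alleles["IGH"])
    j_names = sorted(germ.j_alleles["IGH"])
    v_call = v_names[rng.integers(0, len(v_names))]
    j_call = j_names[rng.integers(0, len(j_names))]
    germline_v = germ.v_alleles["IGH"][v_call]
    junction_len = int(
        germ.junction_lengths[rng.integers(0, len(germ.junction_lengths))]
    )
    junction = _random_nt(rng, junction_len)
    mu = shm.naive_mu if naive else shm.memory_mu
    n_trunk = min(rng.poisson(mu), len(germline_v) // 2)
    pos = rng.choice(len(germline_v), size=n_trunk, replace=False)
    trunk_v = _mutate(germline_v, pos, rng)
    n_variants = 1 + rng.poisson(shm.variants_naive if naive else shm.variants_memory)
    return _BLineage(
        lineage_id=lineage_id,
        naive=naive,
        v_call=v_call,
        j_call=j_call,
        junction=junction,
        trunk_v=trunk_v,
        germline_v=germline_v,
        j_seq=germ.j_alleles["IGH"][j_call],
        n_variants=n_variants,
    )


def _emit_b_records(
    lineage: _BLineage,
    count: int,
    donor_id: str,
    timepoint: str,
    rng: np.random.Generator,
    shm: ShmConfig,
) -> list[Rearrangement]:
    variants = lineage.build_variants(rng, shm)
    k = min(len(variants), count)
    alloc = np.ones(k, dtype=np.int64)
    if count > k:
        alloc += rng.multinomial(count - k, np.full(k, 1.0 / k))
    records = []
    for v_idx in range(k):
        v_region, junction = variants[v_idx]
        records.append(
            Rearrangement(
                sequence_id=f"{donor_id}_{timepoint}_IGH_{lineage.lineage_id}_v{v_idx}",
                locus="IGH",
                v_call=lineage.v_call,
                j_call=lineage.j_call,
                junction=junction,
                duplicate_count=int(alloc[v_idx]),
                productive=True,
                sequence=v_region + junction + lineage.j_seq,
                sequence_alignment=v_region,
                germline_alignment=lineage.germline_v,
                extras={"lineage_id": lineage.lineage_id},
            )
        )
    return records


def _simulate_igh(
    config: ScenarioConfig,
    germ: GermlineSet,
    donor_seed: int,
    donor_id: str,
    cohort: str,
    scenario: Optional[str],
) -> tuple[RepertoireSample, RepertoireSample, pd.DataFrame]:
    depth = config.igh
    shm = config.shm
    bf = config.b_followup
    structure_rng = rng_for(donor_seed, "IGH", "structure")
    counts_rng = rng_for(donor_seed, "IGH", "counts")
    depletion_rng = rng_for(donor_seed, "IGH", "depletion")
    m06_rng = rng_for(donor_seed, "IGH", "m06")

    R = depth.richness
    weights = _zipf_weights(R, config.zipf_s)
    naive_flags = structure_rng.random(R) < shm.naive_fraction
    lineages = [
        _make_b_lineage(f"L{i + 1:05d}", bool(naive_flags[i]), germ, shm, structure_rng)
        for i in range(R)
    ]

    n00 = _lognormal_count(counts_rng, depth.baseline_mean[cohort], depth.sigma)
    counts00 = counts_rng.multinomial(n00, weights)

    m00_records: list[Rearrangement] = []
    for lineage, count in zip(lineages, counts00):
        if count > 0:
            m00_records.extend(
                _emit_b_records(lineage, int(count), donor_id, "M00", counts_rng, shm)
            )

    # --- depletion and follow-up composition -------------------------------
    if cohort == "OCR":
        u = depletion_rng.random(R)
        if scenario == RESIDUAL:
            depleted = np.where(
                naive_flags, u < config.depletion.f_B, u < (1.0 - bf.persistence)
            )
        else:
            depleted = u < config.depletion.f_B
        n06_mean = (
            bf.residual_m06_mean if scenario == RESIDUAL else bf.reconstituted_m06_mean
        )
        n06 = _lognormal_count(m06_rng, n06_mean, bf.m06_sigma)
        new_mass = 0.0
        n_new = 0
        if scenario == RECONSTITUTED:
            n_new = int(round(bf.naive_richness_fraction * n06))
            new_mass = 1.0 if not (~depleted).any() else 1.0 - bf.residual_weight_share
        turnover_like = new_mass
    else:
        depleted = np.zeros(R, dtype=bool)
        n06 = _lognormal_count(m06_rng, depth.baseline_mean[cohort], depth.sigma)
        turnover_like = config.hd_nat_b_turnover
        n_new = int(round(turnover_like * R))
        new_mass = turnover_like if n_new > 0 else 0.0

    surviving = ~depleted
    base_w = weights[surviving]
    new_lineages: list[_BLineage] = []
    if n_new > 0:
        new_lineages = [
            _make_b_lineage(f"N{i + 1:05d}", True, germ, shm, m06_rng)
            for i in range(n_new)
        ]
    if base_w.sum() > 0:
        base_w = base_w / base_w.sum() * (1.0 - new_mass)
    new_w = (
        _zipf_weights(n_new, 0.5) * new_mass if n_new > 0 else np.zeros(0)
    )
    full_w = np.concatenate([base_w, new_w])

    m06_records: list[Rearrangement] = []
    counts06_base = np.zeros(R, dtype=np.int64)
    counts06_new = np.zeros(n_new, dtype=np.int64)
    if full_w.sum() > 0 and n06 > 0:
        counts06 = m06_rng.multinomial(n06, full_w / full_w.sum())
        counts06_base[surviving] = counts06[: surviving.sum()]
        counts06_new = counts06[surviving.sum():]
        for lineage, count in zip(lineages, counts06_base):
            if count > 0:
                m06_records.extend(
                    _emit_b_records(lineage, int(count), donor_id, "M06", m06_rng, shm)
                )
        for lineage, count in zip(new_lineages, counts06_new):
            if count > 0:
                m06_records.extend(
                    _emit_b_records(lineage, int(count), donor_id, "M06", m06_rng, shm)
                )

    truth_rows = []
    for i, lineage in enumerate(lineages):
        truth_rows.append(
            {
                "donor_id": donor_id,
                "cohort": cohort,
                "locus": "IGH",
                "lineage_id": lineage.lineage_id,
                "maturity": "naive" if lineage.naive else "memory",
                "cd20dim": False,
                "vd2": False,
                "depleted": bool(depleted[i]),
                "present_m00": bool(counts00[i] > 0),
                "present_m06": bool(counts06_base[i] > 0),
            }
        )
    for j, lineage in enumerate(new_lineages):
        truth_rows.append(
            {
                "donor_id": donor_id,
                "cohort": cohort,
                "locus": "IGH",
                "lineage_id": lineage.lineage_id,
                "maturity": "naive",
                "cd20dim": False,
                "vd2": False,
                "depleted": False,
                "present_m00": False,
                "present_m06": bool(counts06_new[j] > 0),
            }
        )

    meta = dict(donor_id=donor_id, cohort=cohort, locus="IGH")
    m00 = RepertoireSample(records=m00_records, timepoint="M00", **meta)
    m06 = RepertoireSample(records=m06_records, timepoint="M06", **meta)
    return m00, m06, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# T-cell (TRB / TRD) simulation
# ---------------------------------------------------------------------------


def _simulate_t_locus(
    config: ScenarioConfig,
    germ: GermlineSet,
    locus: str,
    donor_seed: int,
    donor_id: str,
    cohort: str,
) -> tuple[RepertoireSample, RepertoireSample, pd.DataFrame]:
    depth = config.locus_depth(locus)
    structure_rng = rng_for(donor_seed, locus, "structure")
    counts_rng = rng_for(donor_seed, locus, "counts")
    depletion_rng = rng_for(donor_seed, locus, "depletion")
    m06_rng = rng_for(donor_seed, locus, "m06")

    R = depth.richness
    weights = _zipf_weights(R, config.zipf_s)
    v_names = sorted(germ.v_alleles[locus])
    j_names = sorted(germ.j_alleles[locus])

    vd2 = np.zeros(R, dtype=bool)
    if locus == "TRD":
        vd2 = structure_rng.random(R) < config.vd2_fraction
        vd2_alleles = [n for n in v_names if n.split("*")[0] == "TRDV2"]
        other_alleles = [n for n in v_names if n.split("*")[0] != "TRDV2"]

    clones = []
    for i in range(R):
        if locus == "TRD":
            pool = vd2_alleles if vd2[i] else other_alleles
            v_call = pool[structure_rng.integers(0, len(pool))]
        else:
            v_call = v_names[structure_rng.integers(0, len(v_names))]
        j_call = j_names[structure_rng.integers(0, len(j_names))]
        junction_len = int(
            germ.junction_lengths[structure_rng.integers(0, len(germ.junction_lengths))]
        )
        junction = _random_nt(structure_rng, junction_len)
        sequence = germ.v_alleles[locus][v_call] + junction + germ.j_alleles[locus][j_call]
        clones.append((f"T{i + 1:06d}", v_call, j_call, junction, sequence))

    cd20dim = np.zeros(R, dtype=bool)
    if locus == "TRB":
        p_dim = _cd20dim_probabilities(
            R, config.depletion.cd20dim_marginal, config.depletion.cd20dim_logit_slope
        )
        cd20dim = structure_rng.random(R) < p_dim

    n00 = _lognormal_count(counts_rng, depth.baseline_mean[cohort], depth.sigma)
    counts00 = counts_rng.multinomial(n00, weights)

    if cohort == "OCR":
        u = depletion_rng.random(R)
        if locus == "TRB":
            depleted = cd20dim & (u < config.depletion.f_T)
        else:
            depleted = vd2 & (u < config.depletion.f_vd2)
    else:
        depleted = np.zeros(R, dtype=bool)

    surviving = ~depleted
    n06 = _lognormal_count(m06_rng, depth.baseline_mean[cohort], depth.sigma)
    counts06 = np.zeros(R, dtype=np.int64)
    if surviving.any() and n06 > 0:
        w06 = weights[surviving] / weights[surviving].sum()
        counts06[surviving] = m06_rng.multinomial(n06, w06)

    def emit(timepoint: str, counts: np.ndarray) -> list[Rearrangement]:
        records = []
        for (clone_id, v_call, j_call, junction, sequence), count in zip(clones, counts):
            if count > 0:
                records.append(
                    Rearrangement(
                        sequence_id=f"{donor_id}_{timepoint}_{locus}_{clone_id}",
                        locus=locus,
                        v_call=v_call,
                        j_call=j_call,
                        junction=junction,
                        duplicate_count=int(count),
                        productive=True,
                        sequence=sequence,
                        extras={"lineage_id": clone_id},
                    )
                )
        return records

    truth = pd.DataFrame(
        {
            "donor_id": donor_id,
            "cohort": cohort,
            "locus": locus,
            "lineage_id": [c[0] for c in clones],
            "maturity": None,
            "cd20dim": cd20dim,
            "vd2": vd2,
            "depleted": depleted,
            "present_m00": counts00 > 0,
            "present_m06": counts06 > 0,
        }
    )
    meta = dict(donor_id=donor_id, cohort=cohort, locus=locus)
    m00 = RepertoireSample(records=emit("M00", counts00), timepoint="M00", **meta)
    m06 = RepertoireSample(records=emit("M06", counts06), timepoint="M06", **meta)
    return m00, m06, truth


# ---------------------------------------------------------------------------
# donor / cohort entry points
# ---------------------------------------------------------------------------


@dataclass
class DonorSim:
    """One donor's paired samples plus the generating ground truth."""

    donor_id: str
    cohort: str
    scenario: Optional[str]
    m00: dict
    m06: dict
    truth: pd.DataFrame


def simulate_donor(
    config: ScenarioConfig,
    donor_seed: int,
    donor_id: str = "D01",
    cohort: str = "OCR",
    loci: Optional[Sequence[str]] = None,
    germline: Optional[GermlineSet] = None,
) -> DonorSim:
    """Simulate one donor's M00/M06 samples for the requested loci."""
    config.validate()
    germ = germline if germline is not None else build_germline(config.germline)
    loci = tuple(loci) if loci is not None else config.loci
    scenario = None
    if cohort == "OCR":
        scen_rng = rng_for(donor_seed, "scenario")
        scenario = (
            RECONSTITUTED
            if scen_rng.random() < config.b_followup.reconstituted_fraction
            else RESIDUAL
        )
    m00: dict[str, RepertoireSample] = {}
    m06: dict[str, RepertoireSample] = {}
    truths = []
    for locus in loci:
        if locus == "IGH":
            s00, s06, truth = _simulate_igh(
                config, germ, donor_seed, donor_id, cohort, scenario
            )
        else:
            s00, s06, truth = _simulate_t_locus(
                config, germ, locus, donor_seed, donor_id, cohort
            )
        m00[locus] = s00
        m06[locus] = s06
        truths.append(truth)
    return DonorSim(
        donor_id=donor_id,
        cohort=cohort,
        scenario=scenario,
        m00=m00,
        m06=m06,
        truth=pd.concat(truths, ignore_index=True) if truths else pd.DataFrame(),
    )


@dataclass
class CohortSim:
    """Manifest and truth tables of a simulated cohort written to disk."""

    manifest: pd.DataFrame
    truth_lineages: pd.DataFrame
    truth_donors: pd.DataFrame
    out_dir: Path


def simulate_cohort(config: ScenarioConfig, out_dir) -> CohortSim:
    """Simulate and write a full cohort: AIRR TSVs, truth tables, manifest."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    germ = build_germline(config.germline)
    manifest_rows = []
    donor_rows = []
    lineage_truths = []
    for cohort in ("HD", "NAT", "OCR"):
        for i in range(config.n_donors.get(cohort, 0)):
            donor_id = f"{cohort}{i + 1:02d}"
            donor_seed = derive_seed(config.seed, "donor", cohort, i)
            sim = simulate_donor(
                config, donor_seed, donor_id=donor_id, cohort=cohort, germline=germ
            )
            donor_rows.append(
                {"donor_id": donor_id, "cohort": cohort, "scenario": sim.scenario}
            )
            lineage_truths.append(sim.truth)
            for timepoint, samples in (("M00", sim.m00), ("M06", sim.m06)):
                for locus in config.loci:
                    fname = f"{donor_id}_{timepoint}_{locus}.tsv"
                    write_rearrangements(samples[locus], out_dir / fname)
                    manifest_rows.append(
                        {
                            "donor_id": donor_id,
                            "cohort": cohort,
                            "timepoint": timepoint,
                            "locus": locus,
                            "path": fname,
                        }
                    )
    manifest = pd.DataFrame(
        manifest_rows, columns=["donor_id", "cohort", "timepoint", "locus", "path"]
    )
    truth_donors = pd.DataFrame(donor_rows, columns=["donor_id", "cohort", "scenario"])
    truth_lineages = (
        pd.concat(lineage_truths, ignore_index=True)
        if lineage_truths
        else pd.DataFrame()
    )
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    truth_donors.to_csv(out_dir / "truth_donors.tsv", sep="\t", index=False)
    truth_lineages.to_csv(out_dir / "truth_lineages.tsv", sep="\t", index=False)
    return CohortSim(
        manifest=manifest,
        truth_lineages=truth_lineages,
        truth_donors=truth_donors,
        out_dir=out_dir,
    )


# ---------------------------------------------------------------------------
# toy single-cell matrix
# ---------------------------------------------------------------------------


@dataclass
class SubsetSpec:
    """One immune-cell subset in the toy matrix."""

    positive_fraction: float
    resident: bool
    n_cells: int = 400


def _default_subsets() -> dict:
    # baseline marker-positive fractions loosely shaped like CSF subsets:
    # B cells high, plasma cells intermediate, TRM-like T subsets low but >1%
    return {
        "B activated": SubsetSpec(0.60, resident=False),
        "CD4 Tfh": SubsetSpec(0.02, resident=False),
        "CD8 CM": SubsetSpec(0.02, resident=False),
        "Plasmacells": SubsetSpec(0.17, resident=True),
        "CCR5high Th17.1": SubsetSpec(0.03, resident=True),
        "CD8 TRM ITGA1+": SubsetSpec(0.04, resident=True),
    }


@dataclass
class GatingScenario:
    """Parameters of the toy single-cell count matrix."""

    subsets: dict = field(default_factory=_default_subsets)
    samples: tuple = (("P1", "M00"), ("P1", "M06"), ("P2", "M00"), ("P2", "M06"))
    m06_infiltrating_factor: float = 0.1
    false_negative_rate: float = 0.109
    true_positive_fraction: float = 0.838
    marker: str = "MS4A1"
    n_noise_genes: int = 25
    marker_count_mean: float = 1.2
    noise_count_mean: float = 0.2

    def validate(self) -> None:
        probs = [self.m06_infiltrating_factor, self.false_negative_rate,
                 self.true_positive_fraction]
        probs += [s.positive_fraction for s in self.subsets.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("gating scenario probabilities must lie in [0, 1]")


def simulate_cell_matrix(config: GatingScenario, seed: int):
    """Generate a toy genes x cells count matrix with labels.

    Marker positivity per cell is Bernoulli with the subset's baseline
    fraction, multiplied by the depletion factor at M06 for infiltrating
    (non-resident) subsets; resident subsets are unchanged.  Protein labels
    are drawn with the configured RNA/protein concordance.
    """
    from scipy import sparse

    from .ms4a1_gating import CellCounts

    config.validate()
    rng = np.random.default_rng(seed)
    genes = [config.marker] + [f"GENE{i + 1:03d}" for i in range(config.n_noise_genes)]
    cell_ids: list[str] = []
    label_rows = []
    marker_counts: list[int] = []
    noise_blocks: list[np.ndarray] = []
    for sample_id, timepoint in config.samples:
        for subset_name in sorted(config.subsets):
            spec = config.subsets[subset_name]
            p = spec.positive_fraction
            if timepoint != "M00" and not spec.resident:
                p = p * config.m06_infiltrating_factor
            rna_pos = rng.random(spec.n_cells) < p
            protein = np.where(
                rna_pos,
                rng.random(spec.n_cells) < config.true_positive_fraction,
                rng.random(spec.n_cells) < config.false_negative_rate,
            )
            counts = np.where(
                rna_pos, 1 + rng.poisson(config.marker_count_mean, spec.n_cells), 0
            )
            noise = rng.poisson(
                config.noise_count_mean, size=(config.n_noise_genes, spec.n_cells)
            )
            for j in range(spec.n_cells):
                cid = f"{sample_id}_{timepoint}_{subset_name}_{j:04d}".replace(" ", "-")
                cell_ids.append(cid)
                label_rows.append(
                    {
                        "cell_id": cid,
                        "subset": subset_name,
                        "sample_id": sample_id,
                        "timepoint": timepoint,
                        "protein_positive": bool(protein[j]),
                    }
                )
            marker_counts.extend(int(c) for c in counts)
            noise_blocks.append(noise)
    noise_matrix = np.concatenate(noise_blocks, axis=1)
    matrix = np.vstack([np.asarray(marker_counts, dtype=np.int64), noise_matrix])
    return CellCounts(
        counts=sparse.csr_matrix(matrix),
        gene_ids=genes,
        cell_ids=cell_ids,
        labels=pd.DataFrame(label_rows),
    )
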