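"""Synthetic longitudinal V(D)J repertoire generator with known ground truth.

The generator emulates annotated heavy-chain rearrangements from a longitudinal
study design: ``n_subjects`` donors sampled at ``n_timepoints`` timepoints, with
``n_replicates_per_timepoint`` biological replicates of
``n_sequences_per_replicate`` sequences each. Every sequence derives from a
clonal *lineage* (one VDJ rearrangement event) whose identity — V/D/J genes and
junction — is registered in a :class:`GroundTruth` object, so downstream
statistics (persistence, public sharing, gene usage) can be checked by
parameter recovery.

Model summary
-------------
* A lineage draws its V, D and J genes and its CDRH3 length from configurable
  usage distributions, and its junction amino acids from a per-residue
  amino-acid bias (the IMGT junction is ``C`` + CDRH3 + ``W``). The nucleotide
  junction is a random codon realization of the amino-acid junction, standing
  in for the templated V/D/J ends plus non-templated N/P additions.
* A lineage is *naive* (IgM, zero V mutations) with probability
  ``naive_fraction``, otherwise *memory*: per-cell isotype drawn from
  ``memory_isotype_probs`` and per-cell V-gene mutation counts Poisson with
  mean ``shm_rate``; memory cells may additionally carry synonymous
  substitutions in the junction (rate ``junction_mutation_rate`` per codon),
  so nucleotide-sequence identity is a strict refinement of clonotype identity.
* Lineage sizes are heavy-tailed (discrete power law, exponent
  ``lineage_size_exponent``), so expanded lineages are over-sampled.
* Each timepoint's *cell pool* is the exact multiset of lineage cells; the
  biological replicates partition it (disjoint draws without replacement), so
  a clonotype observed in more than one biological replicate necessarily came
  from distinct cells of an expanded lineage.
* A lineage present at one timepoint is carried to the next with probability
  ``persistent_fraction`` (its identity is preserved; its size is redrawn).
* A *public pool* of ``public_pool_size`` clonotype identities is shared by
  all subjects and receives a fraction ``public_pool_weight`` of each
  timepoint's cells; public junction nucleotides are realized independently
  per subject (amino-acid convergence, not nucleotide identity).
* Optional :class:`LineageBias` overrides let persistent or public lineages
  differ systematically (compartment, SHM, IgG probability, CDRH3 length
  shift, lineage-size multiplier), and optional Dirichlet concentrations add
  subject- and timepoint-specific perturbations of the usage distributions.

All randomness flows through one :func:`numpy.random.default_rng` generator
seeded from ``config.seed``; draw order is fixed (public pool, then per
subject: usage perturbations, then per timepoint: lineage census, cell pool
shuffle, per-cell annotations), so identical configs give byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio.Data import CodonTable

from .errors import ConfigurationError

__all__ = [
    "LineageBias",
    "SimulationConfig",
    "GroundTruth",
    "simulate_study",
    "generate_junction",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_PROB_TOL = 1e-9


def _normalized(weights: dict) -> dict:
    total = float(sum(weights.values()))
    return {k: v / total for k, v in weights.items()}


#: Default gene pools: common human IGHV/IGHD/IGHJ genes with plausible
#: relative usage (IGHJ4-dominant J usage, IGHV3-23/IGHV3-30/IGHV4-34 among
#: the most used V genes).
DEFAULT_V_GENE_POOL = _normalized({
    "IGHV1-2": 0.040, "IGHV1-3": 0.015, "IGHV1-8": 0.015, "IGHV1-18": 0.030,
    "IGHV1-46": 0.025, "IGHV1-69": 0.050, "IGHV2-5": 0.020, "IGHV2-70": 0.010,
    "IGHV3-7": 0.035, "IGHV3-9": 0.030, "IGHV3-11": 0.025, "IGHV3-15": 0.025,
    "IGHV3-21": 0.035, "IGHV3-23": 0.090, "IGHV3-30": 0.070, "IGHV3-33": 0.035,
    "IGHV3-43": 0.010, "IGHV3-48": 0.030, "IGHV3-53": 0.025, "IGHV3-74": 0.030,
    "IGHV4-4": 0.020, "IGHV4-31": 0.030, "IGHV4-34": 0.060, "IGHV4-39": 0.050,
    "IGHV4-59": 0.050, "IGHV4-61": 0.020, "IGHV5-51": 0.040, "IGHV6-1": 0.020,
    "IGHV7-4-1": 0.015,
})

DEFAULT_D_GENE_POOL = _normalized({
    "IGHD1-26": 0.08, "IGHD2-2": 0.10, "IGHD2-15": 0.09, "IGHD3-3": 0.12,
    "IGHD3-10": 0.14, "IGHD3-22": 0.12, "IGHD4-17": 0.09, "IGHD5-12": 0.07,
    "IGHD6-13": 0.10, "IGHD6-19": 0.09,
})

DEFAULT_J_GENE_POOL = _normalized({
    "IGHJ1": 0.02, "IGHJ2": 0.03, "IGHJ3": 0.10, "IGHJ4": 0.50,
    "IGHJ5": 0.13, "IGHJ6": 0.22,
})

#: CDRH3s are enriched for small/aromatic residues (Gly, Tyr, Ser, Asp, Arg).
DEFAULT_JUNCTION_AA_BIAS = _normalized({
    "A": 1.5, "C": 0.3, "D": 1.8, "E": 0.8, "F": 1.3, "G": 3.0, "H": 0.6,
    "I": 0.9, "K": 0.7, "L": 1.2, "M": 0.4, "N": 0.8, "P": 0.9, "Q": 0.6,
    "R": 1.8, "S": 2.0, "T": 1.2, "V": 1.2, "W": 0.6, "Y": 2.5,
})


def _default_length_distribution() -> dict:
    """Discretized bell around 15-16 AA over the IMGT CDRH3 range 5-35."""
    lengths = np.arange(5, 36)
    w = np.exp(-0.5 * ((lengths - 15.5) / 3.3) ** 2)
    w /= w.sum()
    return {int(l): float(p) for l, p in zip(lengths, w)}


def _codon_map() -> dict:
    table = CodonTable.unambiguous_dna_by_id[1]
    out: dict[str, list[str]] = {aa: [] for aa in AA_ALPHABET}
    for codon, aa in table.forward_table.items():
        out[aa].append(codon)
    return {aa: sorted(codons) for aa, codons in out.items()}

CODONS_BY_AA = _codon_map()


@dataclass
class LineageBias:
    """Overrides applied to a designated lineage class (persistent or public).

    ``None`` fields fall back to the global config value. ``cdrh3_length_shift``
    moves the sampled CDRH3 length (clipped to the configured support);
    ``size_multiplier`` scales the sampled lineage size.
    """

    naive_fraction: Optional[float] = None
    shm_rate: Optional[float] = None
    igg_prob: Optional[float] = None
    cdrh3_length_shift: int = 0
    size_multiplier: float = 1.0


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic longitudinal repertoire."""

    n_subjects: int = 2
    n_timepoints: int = 2
    n_replicates_per_timepoint: int = 6
    n_sequences_per_replicate: int = 1000
    v_gene_pool: dict = field(default_factory=lambda: dict(DEFAULT_V_GENE_POOL))
    d_gene_pool: dict = field(default_factory=lambda: dict(DEFAULT_D_GENE_POOL))
    j_gene_pool: dict = field(default_factory=lambda: dict(DEFAULT_J_GENE_POOL))
    cdrh3_length_distribution: dict = field(default_factory=_default_length_distribution)
    junction_aa_bias: dict = field(default_factory=lambda: dict(DEFAULT_JUNCTION_AA_BIAS))
    naive_fraction: float = 0.7
    memory_isotype_probs: dict = field(default_factory=lambda: {"IgM": 0.5, "IgG": 0.5})
    shm_rate: float = 6.0
    lineage_size_exponent: float = 2.5
    persistent_fraction: float = 0.02
    public_pool_size: int = 100
    public_pool_weight: float = 0.01
    public_persistent_fraction: Optional[float] = None
    junction_mutation_rate: float = 0.02
    subject_usage_concentration: Optional[float] = None
    timepoint_usage_concentration: Optional[float] = None
    persistent_bias: Optional[LineageBias] = None
    public_bias: Optional[LineageBias] = None
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("n_subjects", "n_timepoints", "n_replicates_per_timepoint",
                     "n_sequences_per_replicate"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("v_gene_pool", "d_gene_pool", "j_gene_pool",
                     "cdrh3_length_distribution", "junction_aa_bias",
                     "memory_isotype_probs"):
            probs = getattr(self, name)
            if not probs:
                raise ConfigurationError(f"{name} must be non-empty")
            vals = np.asarray(list(probs.values()), dtype=float)
            if (vals < 0).any():
                raise ConfigurationError(f"{name} has negative probabilities")
            if abs(vals.sum() - 1.0) > _PROB_TOL:
                raise ConfigurationError(
                    f"{name} probabilities sum to {vals.sum():.12f}, not 1")
        for length in self.cdrh3_length_distribution:
            if not 5 <= int(length) <= 35:
                raise ConfigurationError(
                    f"cdrh3_length_distribution support must lie in 5-35, got {length}")
        for name in ("naive_fraction", "persistent_fraction", "public_pool_weight",
                     "junction_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.public_persistent_fraction is not None and not (
                0.0 <= self.public_persistent_fraction <= 1.0):
            raise ConfigurationError("public_persistent_fraction must be in [0, 1]")
        if self.lineage_size_exponent <= 1.0:
            raise ConfigurationError("lineage_size_exponent must be > 1")
        bad = set(self.memory_isotype_probs) - {"IgM", "IgG"}
        if bad:
            raise ConfigurationError(f"memory_isotype_probs keys must be IgM/IgG, got {bad}")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        for key in ("persistent_bias", "public_bias"):
            if data.get(key) is not None:
                data[key] = LineageBias(**data[key])
        if "cdrh3_length_distribution" in data:
            data["cdrh3_length_distribution"] = {
                int(k): float(v) for k, v in data["cdrh3_length_distribution"].items()}
        return cls(**data)


@dataclass
class GroundTruth:
    """Registry of simulated lineages and the record-to-lineage map.

    ``lineages`` has one row per (subject, lineage): lineage_id, subject,
    v_gene, d_gene, j_gene, cdrh3_aa, clonotype key, compartment, is_public,
    timepoints (';'-joined labels) and is_persistent (present at more than
    one timepoint). ``record_map`` maps every emitted sequence_id to exactly
    one lineage_id.
    """

    lineages: pd.DataFrame
    record_map: pd.DataFrame
    config: SimulationConfig

    def persistent_fraction_observed(self, subject: str, include_public: bool = False) -> float:
        """Fraction of a subject's first-timepoint lineages carried forward."""
        sub = self.lineages[self.lineages["subject"] == subject]
        if not include_public:
            sub = sub[~sub["is_public"]]
        t1 = sub[sub["timepoints"].str.split(";").apply(lambda tps: "T1" in tps)]
        if t1.empty:
            return float("nan")
        return float(t1["is_persistent"].mean())

    def write(self, lineages_path: str | Path, record_map_path: str | Path) -> None:
        self.lineages.to_csv(lineages_path, sep="\t", index=False)
        self.record_map.to_csv(record_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# junction generation


def generate_junction(length_dist: dict, junction_aa_bias: dict,
                      rng: np.random.Generator,
                      length_shift: int = 0) -> tuple[str, str]:
    """Draw one IMGT junction as an (amino-acid, nucleotide) pair.

    The CDRH3 length is drawn from ``length_dist`` (support within 5-35 AA,
    optionally shifted and clipped to the support range); the junction is
    ``C`` + CDRH3 + ``W`` with interior residues drawn i.i.d. from
    ``junction_aa_bias``. The nucleotide junction is a uniform codon
    realization, so it translates exactly to the amino-acid junction and
    contains no stop codons.
    """
    if not length_dist:
        raise ConfigurationError("cdrh3_length_distribution must be non-empty")
    lengths = np.fromiter(length_dist.keys(), dtype=int)
    probs = np.fromiter(length_dist.values(), dtype=float)
    if (lengths < 5).any() or (lengths > 35).any():
        raise ConfigurationError("requested CDRH3 length outside configured support 5-35")
    length = int(rng.choice(lengths, p=probs / probs.sum()))
    if length_shift:
        length = int(np.clip(length + length_shift, lengths.min(), lengths.max()))
    aas = sorted(junction_aa_bias)
    weights = np.asarray([junction_aa_bias[a] for a in aas], dtype=float)
    interior = "".join(rng.choice(list(aas), size=length, p=weights / weights.sum()))
    junction_aa = "C" + interior + "W"
    junction_nt = "".join(
        CODONS_BY_AA[aa][rng.integers(len(CODONS_BY_AA[aa]))] for aa in junction_aa)
    return junction_aa, junction_nt


# ---------------------------------------------------------------------------
# simulation internals


def _perturb(probs: dict, concentration: Optional[float], rng: np.random.Generator) -> dict:
    """Dirichlet perturbation of a probability vector; None = unchanged."""
    if concentration is None:
        return dict(probs)
    keys = list(probs)
    alpha = np.asarray([probs[k] for k in keys], dtype=float) * float(concentration)
    alpha = np.maximum(alpha, 1e-6)
    drawn = rng.dirichlet(alpha)
    return dict(zip(keys, drawn))


def _draw_sizes(n: int, exponent: float, rng: np.random.Generator,
                multiplier: float = 1.0) -> np.ndarray:
    """Heavy-tailed lineage sizes: discrete power law P(s) ~ s^-exponent."""
    sizes = rng.zipf(exponent, size=n)
    sizes = np.minimum(sizes, 10_000)  # guard against astronomically large draws
    if multiplier != 1.0:
        sizes = np.maximum(1, np.round(sizes * multiplier).astype(int))
    return sizes.astype(int)


def _fit_sizes_to_capacity(sizes: np.ndarray, capacity: int) -> np.ndarray:
    """Shrink sizes (keeping every lineage >= 1 cell) until they fit capacity."""
    sizes = sizes.copy()
    if sizes.sum() <= capacity:
        return sizes
    if len(sizes) > capacity:
        raise ConfigurationError(
            f"cannot place {len(sizes)} persistent lineages in a pool of {capacity} cells; "
            "increase n_sequences_per_replicate")
    scaled = np.maximum(1, np.floor(sizes * capacity / sizes.sum()).astype(int))
    while scaled.sum() > capacity:  # floor can overshoot when many sizes hit the 1 floor
        excess = scaled.sum() - capacity
        reducible = np.flatnonzero(scaled > 1)
        take = reducible[:excess]
        scaled[take] -= 1
        if len(take) == 0:
            break
    return scaled


@dataclass
class _Lineage:
    lineage_id: str
    subject: str
    v_gene: str
    d_gene: str
    j_gene: str
    junction_aa: str
    junction_nt: str
    compartment: str   # "naive" | "memory"
    igg_prob: float
    shm_rate: float
    is_public: bool
    public_id: str
    timepoints: list

    @property
    def cdrh3_aa(self) -> str:
        return self.junction_aa[1:-1]


def _sample_gene(pool: dict, rng: np.random.Generator) -> str:
    keys = list(pool)
    probs = np.asarray([pool[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _make_lineage(lid: str, subject: str, dists: dict, cfg: SimulationConfig,
                  bias: Optional[LineageBias], rng: np.random.Generator,
                  is_public: bool = False, public_id: str = "",
                  identity: Optional[tuple] = None) -> _Lineage:
    """Create a lineage; ``identity`` reuses a public (V, D, J, junction_aa)."""
    bias = bias or LineageBias()
    if identity is not None:
        v, d, j, junction_aa = identity
        junction_nt = "".join(
            CODONS_BY_AA[aa][rng.integers(len(CODONS_BY_AA[aa]))] for aa in junction_aa)
    else:
        v = _sample_gene(dists["v"], rng)
        d = _sample_gene(cfg.d_gene_pool, rng)
        j = _sample_gene(dists["j"], rng)
        junction_aa, junction_nt = generate_junction(
            dists["length"], cfg.junction_aa_bias, rng, bias.cdrh3_length_shift)
    naive_p = cfg.naive_fraction if bias.naive_fraction is None else bias.naive_fraction
    compartment = "naive" if rng.random() < naive_p else "memory"
    igg = cfg.memory_isotype_probs.get("IgG", 0.0) if bias.igg_prob is None else bias.igg_prob
    shm = cfg.shm_rate if bias.shm_rate is None else bias.shm_rate
    return _Lineage(lid, subject, v, d, j, junction_aa, junction_nt, compartment,
                    float(igg), float(shm), is_public, public_id, [])


# flat codon lookup tables for batched codon realization
_AA_TO_IDX = {a: i for i, a in enumerate(AA_ALPHABET)}
_N_CODONS = np.asarray([len(CODONS_BY_AA[a]) for a in AA_ALPHABET])
_CODON_OFFSET = np.concatenate([[0], np.cumsum(_N_CODONS)[:-1]])
_CODON_FLAT = np.asarray([c for a in AA_ALPHABET for c in CODONS_BY_AA[a]], dtype=object)


def _batch_codon_realize(aa_strings: list, rng: np.random.Generator) -> list:
    """Uniform codon realization of many amino-acid strings at once."""
    lens = np.asarray([len(s) for s in aa_strings])
    total = int(lens.sum())
    flat_idx = np.fromiter((_AA_TO_IDX[a] for s in aa_strings for a in s),
                           dtype=int, count=total)
    draws = rng.integers(0, _N_CODONS[flat_idx])
    codons = _CODON_FLAT[_CODON_OFFSET[flat_idx] + draws]
    out, pos = [], 0
    for length in lens:
        out.append("".join(codons[pos:pos + length]))
        pos += length
    return out


def _batch_junctions(n: int, length_dist: dict, aa_bias: dict,
                     rng: np.random.Generator, length_shift: int = 0):
    """Batched :func:`generate_junction`: n (aa, nt) junction pairs."""
    support = np.fromiter(length_dist.keys(), dtype=int)
    probs = np.fromiter(length_dist.values(), dtype=float)
    lengths = rng.choice(support, size=n, p=probs / probs.sum())
    if length_shift:
        lengths = np.clip(lengths + length_shift, support.min(), support.max())
    aas = sorted(aa_bias)
    weights = np.asarray([aa_bias[a] for a in aas], dtype=float)
    interior = rng.choice(np.asarray(aas), size=int(lengths.sum()),
                          p=weights / weights.sum())
    aa_strings, pos = [], 0
    for length in lengths:
        aa_strings.append("C" + "".join(interior[pos:pos + length]) + "W")
        pos += length
    return aa_strings, _batch_codon_realize(aa_strings, rng)


def _batch_make_lineages(ids: list, subject: str, dists: dict, cfg: SimulationConfig,
                         bias: Optional[LineageBias], rng: np.random.Generator) -> list:
    """Create many private lineages with shared bias in one vectorized pass."""
    bias = bias or LineageBias()
    n = len(ids)
    draws = {}
    for name, pool in (("v", dists["v"]), ("d", cfg.d_gene_pool), ("j", dists["j"])):
        keys = np.asarray(list(pool), dtype=object)
        probs = np.asarray(list(pool.values()), dtype=float)
        draws[name] = keys[rng.choice(len(keys), size=n, p=probs / probs.sum())]
    aa, nt = _batch_junctions(n, dists["length"], cfg.junction_aa_bias, rng,
                              bias.cdrh3_length_shift)
    naive_p = cfg.naive_fraction if bias.naive_fraction is None else bias.naive_fraction
    naive = rng.random(n) < naive_p
    igg = cfg.memory_isotype_probs.get("IgG", 0.0) if bias.igg_prob is None else bias.igg_prob
    shm = cfg.shm_rate if bias.shm_rate is None else bias.shm_rate
    return [
        _Lineage(ids[i], subject, str(draws["v"][i]), str(draws["d"][i]),
                 str(draws["j"][i]), aa[i], nt[i],
                 "naive" if naive[i] else "memory", float(igg), float(shm),
                 False, "", [])
        for i in range(n)
    ]


def _mutate_junction_synonymously(nt: str, n_subs: int, rng: np.random.Generator) -> str:
    """Replace ``n_subs`` random codons by synonymous codons (AA unchanged)."""
    codons = [nt[i:i + 3] for i in range(0, len(nt), 3)]
    table = CodonTable.unambiguous_dna_by_id[1].forward_table
    positions = rng.choice(len(codons), size=min(n_subs, len(codons)), replace=False)
    for pos in positions:
        aa = table.get(codons[pos])
        if aa is None:
            continue
        options = CODONS_BY_AA[aa]
        if len(options) > 1:
            codons[pos] = options[rng.integers(len(options))]
    return "".join(codons)


def simulate_study(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the full study and return (records, ground truth).

    Records form a validated repertoire DataFrame (one row per sequence,
    AIRR-style columns plus provenance and derived columns); the ground truth
    registers every lineage and maps every sequence_id to its lineage.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    subjects = [f"S{i + 1}" for i in range(cfg.n_subjects)]
    timepoints = [f"T{i + 1}" for i in range(cfg.n_timepoints)]
    replicates = [f"R{i + 1}" for i in range(cfg.n_replicates_per_timepoint)]
    n_cells = cfg.n_replicates_per_timepoint * cfg.n_sequences_per_replicate

    # 1. public pool identities, shared verbatim (V, D, J, CDRH3 AA) by all subjects
    base_dists = {"v": cfg.v_gene_pool, "j": cfg.j_gene_pool,
                  "length": cfg.cdrh3_length_distribution}
    public_identities = []
    pb = cfg.public_bias or LineageBias()
    for _ in range(cfg.public_pool_size if cfg.public_pool_weight > 0 else 0):
        v = _sample_gene(cfg.v_gene_pool, rng)
        d = _sample_gene(cfg.d_gene_pool, rng)
        j = _sample_gene(cfg.j_gene_pool, rng)
        aa, _ = generate_junction(cfg.cdrh3_length_distribution, cfg.junction_aa_bias,
                                  rng, pb.cdrh3_length_shift)
        public_identities.append((v, d, j, aa))

    p_persist_public = (cfg.persistent_fraction if cfg.public_persistent_fraction is None
                        else cfg.public_persistent_fraction)

    record_frames = []
    lineage_rows = []
    record_map_rows = []
    lineage_counter = 0

    for subject in subjects:
        subj_dists = {
            "v": _perturb(base_dists["v"], cfg.subject_usage_concentration, rng),
            "j": _perturb(base_dists["j"], cfg.subject_usage_concentration, rng),
            "length": _perturb(base_dists["length"], cfg.subject_usage_concentration, rng),
        }
        # per-subject realizations of the public identities
        public_lineages = []
        for k, ident in enumerate(public_identities):
            lin = _make_lineage(f"{subject}_P{k:05d}", subject, subj_dists, cfg,
                                cfg.public_bias, rng, is_public=True,
                                public_id=f"PUB{k:05d}", identity=ident)
            public_lineages.append(lin)
        public_persist_flags = rng.random(len(public_lineages)) < p_persist_public

        carried: list[_Lineage] = []          # persistent lineages entering this timepoint
        carried_public: list[_Lineage] = []
        all_lineages: dict[str, _Lineage] = {}

        for tp in timepoints:
            tp_dists = {
                "v": _perturb(subj_dists["v"], cfg.timepoint_usage_concentration, rng),
                "j": _perturb(subj_dists["j"], cfg.timepoint_usage_concentration, rng),
                "length": _perturb(subj_dists["length"], cfg.timepoint_usage_concentration, rng),
            }
            n_public_cells = int(round(cfg.public_pool_weight * n_cells)) if public_identities else 0

            census: list[_Lineage] = []
            sizes: list[int] = []

            # public cells: at the first timepoint over the whole pool, later
            # only over the public lineages that persisted
            pool_now = public_lineages if tp == timepoints[0] else carried_public
            if n_public_cells and pool_now:
                pub_mult = (cfg.public_bias.size_multiplier if cfg.public_bias else 1.0)
                pub_sizes = _draw_sizes(len(pool_now), cfg.lineage_size_exponent, rng, pub_mult)
                alloc = rng.multinomial(n_public_cells, pub_sizes / pub_sizes.sum())
                for lin, k in zip(pool_now, alloc):
                    if k > 0:
                        census.append(lin)
                        sizes.append(int(k))
            private_capacity = n_cells - int(np.sum(sizes))

            # persistent private lineages carried from the previous timepoint
            carried_start = len(sizes)
            if carried:
                mult = (cfg.persistent_bias.size_multiplier if cfg.persistent_bias else 1.0)
                csizes = _draw_sizes(len(carried), cfg.lineage_size_exponent, rng, mult)
                csizes = _fit_sizes_to_capacity(csizes, private_capacity)
                census.extend(carried)
                sizes.extend(int(s) for s in csizes)
                private_capacity -= int(csizes.sum())

            if cfg.persistent_fraction >= 1.0 and carried and private_capacity > 0:
                # static pool: no fresh recruitment, leftover capacity
                # redistributes over the carried lineages
                w = np.asarray(sizes[carried_start:], dtype=float)
                extra = rng.multinomial(private_capacity, w / w.sum())
                for k, e in enumerate(extra):
                    sizes[carried_start + k] += int(e)
                private_capacity = 0

            # fresh private lineages fill the remaining capacity exactly
            while private_capacity > 0:
                batch = max(32, private_capacity // 2 + 1)
                flags = rng.random(batch) < cfg.persistent_fraction
                base_sizes = _draw_sizes(batch, cfg.lineage_size_exponent, rng)
                if cfg.persistent_bias is not None and cfg.persistent_bias.size_multiplier != 1.0:
                    scaled = np.maximum(
                        1, np.round(base_sizes * cfg.persistent_bias.size_multiplier)).astype(int)
                    batch_sizes = np.where(flags, scaled, base_sizes)
                else:
                    batch_sizes = base_sizes
                n_take = int(np.searchsorted(np.cumsum(batch_sizes), private_capacity))
                if n_take < batch:
                    n_take += 1  # one more lineage, clipped to fit exactly
                take_sizes = batch_sizes[:n_take].copy()
                overshoot = int(take_sizes.sum()) - private_capacity
                if overshoot > 0:
                    take_sizes[-1] -= overshoot
                take_flags = flags[:n_take].copy()
                if take_sizes[-1] == 0:
                    take_sizes, take_flags = take_sizes[:-1], take_flags[:-1]
                for flag_val in (False, True):
                    idx = np.flatnonzero(take_flags == flag_val)
                    if len(idx) == 0:
                        continue
                    ids = [f"{subject}_L{lineage_counter + k:07d}" for k in range(len(idx))]
                    lineage_counter += len(idx)
                    bias = cfg.persistent_bias if flag_val else None
                    for lin, s in zip(_batch_make_lineages(ids, subject, tp_dists, cfg, bias, rng),
                                      take_sizes[idx]):
                        lin._persist_next = bool(flag_val)  # type: ignore[attr-defined]
                        census.append(lin)
                        sizes.append(int(s))
                private_capacity -= int(take_sizes.sum())

            for lin in census:
                lin.timepoints.append(tp)
                all_lineages[lin.lineage_id] = lin

            # 2. cell pool = exact multiset of lineage cells, shuffled, then
            #    partitioned into disjoint biological replicates
            lineage_idx = np.repeat(np.arange(len(census)), sizes)
            rng.shuffle(lineage_idx)
            assert len(lineage_idx) == n_cells

            lin_igg = np.asarray([lin.igg_prob for lin in census])
            lin_shm = np.asarray([lin.shm_rate for lin in census])
            lin_memory = np.asarray([lin.compartment == "memory" for lin in census])
            lin_nt = np.asarray([lin.junction_nt for lin in census], dtype=object)
            lin_aa = np.asarray([lin.junction_aa for lin in census], dtype=object)
            lin_v = np.asarray([lin.v_gene for lin in census], dtype=object)
            lin_d = np.asarray([lin.d_gene for lin in census], dtype=object)
            lin_j = np.asarray([lin.j_gene for lin in census], dtype=object)
            lin_ids = np.asarray([lin.lineage_id for lin in census], dtype=object)

            memory_cell = lin_memory[lineage_idx]
            isotype = np.where(memory_cell & (rng.random(n_cells) < lin_igg[lineage_idx]),
                               "IgG", "IgM")
            v_mut = np.where(memory_cell, rng.poisson(lin_shm[lineage_idx]), 0)
            junction_nt_cells = lin_nt[lineage_idx].copy()
            n_codons = np.char.str_len(junction_nt_cells.astype(str)) // 3
            syn_subs = np.where(memory_cell,
                                rng.binomial(n_codons, cfg.junction_mutation_rate), 0)
            for i in np.flatnonzero(syn_subs > 0):
                junction_nt_cells[i] = _mutate_junction_synonymously(
                    junction_nt_cells[i], int(syn_subs[i]), rng)

            rep_labels = np.repeat(replicates, cfg.n_sequences_per_replicate)
            seq_ids = np.asarray(
                [f"{subject}_{tp}_{rep_labels[i]}_{i % cfg.n_sequences_per_replicate:06d}"
                 for i in range(n_cells)], dtype=object)

            frame = pd.DataFrame({
                "sequence_id": seq_ids,
                "subject": subject,
                "timepoint": tp,
                "replicate": rep_labels,
                "v_call": lin_v[lineage_idx],
                "d_call": lin_d[lineage_idx],
                "j_call": lin_j[lineage_idx],
                "junction": junction_nt_cells,
                "junction_aa": lin_aa[lineage_idx],
                "isotype": isotype,
                "v_mutation_count": v_mut.astype(int),
                "duplicate_count": 1,
            })
            record_frames.append(frame)
            record_map_rows.append(pd.DataFrame({
                "sequence_id": seq_ids,
                "lineage_id": lin_ids[lineage_idx],
            }))

            # 3. decide which lineages persist to the next timepoint
            carried = [lin for lin in census
                       if not lin.is_public and getattr(lin, "_persist_next", False)]
            # a carried lineage stays persistent for exactly one transition
            for lin in carried:
                lin._persist_next = False  # type: ignore[attr-defined]
            carried_public = [lin for lin, flag in zip(public_lineages, public_persist_flags)
                              if flag and lin.timepoints]

        for lin in all_lineages.values():
            lineage_rows.append({
                "lineage_id": lin.lineage_id,
                "subject": lin.subject,
                "v_gene": lin.v_gene,
                "d_gene": lin.d_gene,
                "j_gene": lin.j_gene,
                "cdrh3_aa": lin.cdrh3_aa,
                "clonotype": f"{lin.v_gene}|{lin.j_gene}|{lin.cdrh3_aa}",
                "compartment": lin.compartment,
                "is_public": lin.is_public,
                "public_id": lin.public_id,
                "timepoints": ";".join(lin.timepoints),
                "is_persistent": len(lin.timepoints) > 1,
            })

    records = pd.concat(record_frames, ignore_index=True)
    from .io import add_derived_columns
    records = add_derived_columns(records)
    records.attrs["dropped_rows"] = 0
    truth = GroundTruth(
        lineages=pd.DataFrame(lineage_rows),
        record_map=pd.concat(record_map_rows, ignore_index=True),
        config=cfg,
    )
    return records, truth
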