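"""Synthetic bone-sample search-result cohorts with realistic error structure.

The generator emulates the *search-result* layer of a collagen MS/MS
experiment, not the spectra themselves: per-sample spectrum counts in the
observed range (79-710), redundant spectra per peptide sequence (mean ~5.7),
~80% of spectra attributed to the correct species, wrong-species
identifications split into isobaric (36%) and non-isobaric (64%) classes, the
non-isobaric ones into single (64%) and multiple (36%) amino-acid changes,
class-dependent E-value distributions, equal-E-value alternative peptides per
spectrum (17% two, 1.6% three, 0.5% four), ~92% of correct peptides shared
with other species, occasional decoy hits, and database-representation skew —
a species with (near) zero database weight loses its attributions to well
represented neighbours, reproducing the deer-identified-as-sheep failure mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .psm_io import SampleResult, SpectrumMatch, TaxonomyTable, normalize_species
from .substitution import min_nt_changes
from pyteomics import mass as pmass

__all__ = [
    "CohortConfig",
    "SpeciesSpec",
    "default_species_table",
    "generate_consensus",
    "generate_sample",
    "generate_cohort",
]


@dataclass(frozen=True)
class SpeciesSpec:
    species: str
    order: str
    class_: str
    db_entries: int
    n_samples: int


def default_species_table() -> list[SpeciesSpec]:
    """The default cohort composition: 58 samples, 18 taxonomic groups.

    Fifteen known species plus one bird, one fish and one frog of unknown
    species; two additional ovicaprid samples (unknown sheep-or-goat) are
    generated from sheep. Database-entry counts skew heavily: white-tailed
    deer, black bear, river otter, grey squirrel, woodchuck and opossum are
    barely represented, which is what drives their misidentification.
    """
    S = SpeciesSpec
    return [
        S("Homo sapiens", "Primates", "Mammalia", 60000, 19),
        S("Macaca mulatta", "Primates", "Mammalia", 40000, 1),
        S("Ovis aries", "Artiodactyla", "Mammalia", 34779, 3),
        S("Capra hircus", "Artiodactyla", "Mammalia", 20000, 0),
        S("Bos taurus", "Artiodactyla", "Mammalia", 50000, 3),
        S("Sus scrofa", "Artiodactyla", "Mammalia", 30000, 3),
        S("Odocoileus virginianus", "Artiodactyla", "Mammalia", 89, 4),
        S("Pantholops hodgsonii", "Artiodactyla", "Mammalia", 15000, 0),
        S("Equus caballus", "Perissodactyla", "Mammalia", 30000, 3),
        S("Canis lupus familiaris", "Carnivora", "Mammalia", 40000, 3),
        S("Felis catus", "Carnivora", "Mammalia", 30000, 2),
        S("Ursus americanus", "Carnivora", "Mammalia", 80, 1),
        S("Lontra canadensis", "Carnivora", "Mammalia", 60, 1),
        S("Sciurus carolinensis", "Rodentia", "Mammalia", 70, 1),
        S("Marmota monax", "Rodentia", "Mammalia", 50, 1),
        S("Oryctolagus cuniculus", "Lagomorpha", "Mammalia", 25000, 2),
        S("Didelphis virginiana", "Didelphimorphia", "Mammalia", 60, 1),
        S("Sarcophilus harrisii", "Dasyuromorphia", "Mammalia", 20000, 0),
        S("Gallus gallus", "Galliformes", "Aves", 40000, 3),
        S("Danio rerio", "Cypriniformes", "Actinopterygii", 40000, 3),
        S("Xenopus laevis", "Anura", "Amphibia", 30000, 2),
    ]


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort; defaults mirror the observed data."""

    species_table: list[SpeciesSpec] = field(default_factory=default_species_table)
    n_ovicaprid: int = 2  # unknown-species samples generated from sheep
    spectra_range: tuple[int, int] = (79, 710)
    mean_spectra_per_sequence: float = 5.7
    correct_rate: float = 0.8
    isobaric_fraction: float = 0.36  # of wrong-species identifications
    one_aa_fraction: float = 0.64  # of non-isobaric identifications
    sharedness: float = 0.92  # correct peptides shared with other species
    multi_peptide_rates: tuple[float, float, float] = (0.17, 0.016, 0.005)
    decoy_rate: float = 0.004  # expected decoys per target spectrum
    high_e_rate: float = 0.05  # extra junk spectra with E in (0.01, 0.1)
    # log10-uniform E-value ranges per class; medians ordered
    # correct ~ isobaric < non-isobaric 1 AA < non-isobaric >1 AA
    e_ranges: dict = field(
        default_factory=lambda: {
            "correct": (1e-8, 1e-2),
            "isobaric": (1e-8, 1e-2),
            "non_isobaric_1aa": (1e-5, 1e-2),
            "non_isobaric_multi_aa": (1e-4, 1e-2),
        }
    )
    consensus_pool_size: int = 150
    class_divergence: float = 0.5  # per-peptide substitution prob between classes
    order_divergence: float = 0.25  # between orders within a class
    species_divergence: float = 0.10  # between species within an order
    same_order_boost: float = 3.0  # attribution pull toward related species
    # a correct peptide is attributed to its own species with probability
    # db_entries / (db_entries + representation_scale): poorly represented
    # species lose their attributions to well represented neighbours
    representation_scale: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in [
            ("correct_rate", self.correct_rate),
            ("isobaric_fraction", self.isobaric_fraction),
            ("one_aa_fraction", self.one_aa_fraction),
            ("sharedness", self.sharedness),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if not self.species_table:
            raise ValueError("species_table must be non-empty")

    def taxonomy(self) -> TaxonomyTable:
        df = pd.DataFrame(
            [
                {
                    "species": s.species,
                    "order": s.order,
                    "class": s.class_,
                    "db_entries": s.db_entries,
                }
                for s in self.species_table
            ]
        )
        return TaxonomyTable.from_frame(df)


# ---------------------------------------------------------------------------
# consensus peptide pools

_GLY_PARTNERS = "PARKEDSQLIVFNT"  # X/Y positions of collagen G-X-Y repeats

# residues reachable by exactly one nucleotide change, excluding isobaric I/L
def _snp_neighbours() -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for a in aas:
        out[a] = [
            b
            for b in aas
            if b != a
            and min_nt_changes(a, b) == 1
            and abs(pmass.std_aa_mass[a] - pmass.std_aa_mass[b]) > 0.05
        ]
    return out


_SNP = _snp_neighbours()


def _random_peptide(rng: np.random.Generator) -> str:
    n_triplets = int(rng.integers(3, 7))
    parts = []
    for _ in range(n_triplets):
        parts.append("G")
        parts.append(_GLY_PARTNERS[rng.integers(len(_GLY_PARTNERS))])
        parts.append(_GLY_PARTNERS[rng.integers(len(_GLY_PARTNERS))])
    parts.append("KR"[rng.integers(2)])  # tryptic C-terminus
    return "".join(parts)


def _mutate(peptide: str, rng: np.random.Generator) -> str:
    """One substitution: isobaric or single-nucleotide-reachable change."""
    pos = int(rng.integers(len(peptide)))
    aa = peptide[pos]
    if aa in "IL" and rng.random() < 0.3:
        new = "L" if aa == "I" else "I"
    else:
        choices = _SNP[aa]
        new = choices[rng.integers(len(choices))] if choices else aa
    return peptide[:pos] + new + peptide[pos + 1 :]


def generate_consensus(
    config: CohortConfig, seed: int | None = None
) -> dict[str, list[str]]:
    """Per-species consensus pools evolved from one ancestral peptide pool.

    Homologous slots stay index-aligned across species, so a peptide left
    unchanged on every branch is shared identically — close relatives share
    more peptides than distant ones, mimicking collagen conservation.
    """
    if len(config.species_table) < 2:
        raise ValueError("need at least two species")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ancestral = [_random_peptide(rng) for _ in range(config.consensus_pool_size)]

    def diverge(pool: list[str], rate: float) -> list[str]:
        return [_mutate(p, rng) if rng.random() < rate else p for p in pool]

    classes = sorted({s.class_ for s in config.species_table})
    class_pools = {c: diverge(ancestral, config.class_divergence) for c in classes}
    orders = sorted({(s.class_, s.order) for s in config.species_table})
    order_pools = {
        (c, o): diverge(class_pools[c], config.order_divergence) for c, o in orders
    }
    pools = {}
    for s in sorted(config.species_table, key=lambda s: s.species):
        pools[normalize_species(s.species)] = diverge(
            order_pools[(s.class_, s.order)], config.species_divergence
        )
    return pools


# ---------------------------------------------------------------------------
# sample generation

def _isobaric_variant(peptide: str, rng: np.random.Generator) -> str | None:
    """I/L swap if possible, else an adjacent inversion of distinct residues."""
    il = [i for i, aa in enumerate(peptide) if aa in "IL"]
    if il:
        i = il[int(rng.integers(len(il)))]
        swap = "L" if peptide[i] == "I" else "I"
        return peptide[:i] + swap + peptide[i + 1 :]
    pairs = [i for i in range(len(peptide) - 1) if peptide[i] != peptide[i + 1]]
    if not pairs:
        return None
    i = pairs[int(rng.integers(len(pairs)))]
    return peptide[:i] + peptide[i + 1] + peptide[i] + peptide[i + 2 :]


def _non_isobaric_variant(
    peptide: str, n_changes: int, rng: np.random.Generator
) -> str:
    positions = rng.choice(len(peptide), size=min(n_changes, len(peptide)), replace=False)
    out = list(peptide)
    for pos in positions:
        choices = _SNP[out[pos]]
        if not choices:
            continue
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


class _Attributor:
    """Draws species sets honouring database-representation weights."""

    def __init__(self, config: CohortConfig):
        self.specs = {normalize_species(s.species): s for s in config.species_table}
        self.config = config

    def _weights(self, exclude: str, prefer_order: str | None) -> tuple[list[str], np.ndarray]:
        names, w = [], []
        for key, spec in self.specs.items():
            if key == exclude or spec.db_entries <= 0:
                continue
            boost = (
                self.config.same_order_boost
                if prefer_order is not None and spec.order == prefer_order
                else 1.0
            )
            names.append(key)
            w.append(spec.db_entries * boost)
        w = np.asarray(w, dtype=float)
        return names, w / w.sum()

    def correct_set(self, true_species: str, rng: np.random.Generator) -> frozenset[str]:
        spec = self.specs[true_species]
        p_retain = spec.db_entries / (spec.db_entries + self.config.representation_scale)
        out = {true_species} if rng.random() < p_retain else set()
        shared = rng.random() < self.config.sharedness
        if shared or not out:
            names, p = self._weights(true_species, spec.order)
            k = int(rng.integers(1, 4))
            out |= set(rng.choice(names, size=min(k, len(names)), replace=False, p=p))
        return frozenset(out)

    def wrong_set(self, true_species: str, rng: np.random.Generator) -> frozenset[str]:
        spec = self.specs[true_species]
        names, p = self._weights(true_species, spec.order)
        k = int(rng.integers(1, 3))
        return frozenset(rng.choice(names, size=min(k, len(names)), replace=False, p=p))


def generate_sample(
    true_species: str,
    config: CohortConfig,
    seed: int | np.random.Generator = 0,
    sample_id: str = "S1",
    pools: dict[str, list[str]] | None = None,
) -> SampleResult:
    """One synthetic bone sample's (pre-filter) search-result table."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    key = normalize_species(true_species)
    if pools is None:
        pools = generate_consensus(config)
    if key not in pools:
        raise ValueError(f"species {true_species!r} not in taxonomy")
    pool = pools[key]
    attributor = _Attributor(config)
    spec = attributor.specs[key]

    n_spectra = int(rng.integers(config.spectra_range[0], config.spectra_range[1] + 1))
    # redundancy: spectra per sequence ~ shifted geometric, mean ~5.7
    p_geom = 1.0 / config.mean_spectra_per_sequence
    matches: list[SpectrumMatch] = []
    spectrum_no = 0
    produced = 0
    while produced < n_spectra:
        base = pool[int(rng.integers(len(pool)))]
        u = rng.random()
        if u < config.correct_rate:
            klass = "correct"
        elif u < config.correct_rate + (1 - config.correct_rate) * config.isobaric_fraction:
            klass = "isobaric"
        else:
            klass = (
                "non_isobaric_1aa"
                if rng.random() < config.one_aa_fraction
                else "non_isobaric_multi_aa"
            )
        if klass == "correct":
            peptide = base
            species = attributor.correct_set(key, rng)
        elif klass == "isobaric":
            peptide = _isobaric_variant(base, rng) or _non_isobaric_variant(base, 1, rng)
            species = attributor.wrong_set(key, rng)
        elif klass == "non_isobaric_1aa":
            peptide = _non_isobaric_variant(base, 1, rng)
            species = attributor.wrong_set(key, rng)
        else:
            peptide = _non_isobaric_variant(base, 2, rng)
            species = attributor.wrong_set(key, rng)
        n_copies = min(int(rng.geometric(p_geom)), n_spectra - produced)
        lo, hi = config.e_ranges[klass]
        p2, p3, p4 = config.multi_peptide_rates
        for _ in range(n_copies):
            spectrum_no += 1
            sid = f"sp{spectrum_no:05d}"
            e_value = _log_uniform(rng, lo, hi)
            matches.append(
                SpectrumMatch(sample_id, sid, peptide, e_value, False, species)
            )
            # equal-E alternative peptides for this spectrum
            u2 = rng.random()
            n_alt = 3 if u2 < p4 else 2 if u2 < p4 + p3 else 1 if u2 < p4 + p3 + p2 else 0
            alt = peptide
            for _ in range(n_alt):
                alt_candidate = _isobaric_variant(alt, rng)
                if alt_candidate is None or alt_candidate == peptide:
                    break
                alt = alt_candidate
                matches.append(
                    SpectrumMatch(
                        sample_id, sid, alt, e_value, False,
                        attributor.wrong_set(key, rng),
                    )
                )
        produced += n_copies

    # junk target spectra above the E cap (X! Tandem reports up to E < 0.1)
    n_junk = int(rng.poisson(config.high_e_rate * n_spectra))
    for j in range(n_junk):
        spectrum_no += 1
        matches.append(
            SpectrumMatch(
                sample_id,
                f"sp{spectrum_no:05d}",
                _non_isobaric_variant(pool[int(rng.integers(len(pool)))], 2, rng),
                _log_uniform(rng, 0.011, 0.1),
                False,
                attributor.wrong_set(key, rng),
            )
        )
    # decoy hits: rare, often absent entirely
    n_decoys = int(rng.poisson(config.decoy_rate * n_spectra))
    for j in range(n_decoys):
        matches.append(
            SpectrumMatch(
                sample_id,
                f"decoy{j + 1:03d}",
                pool[int(rng.integers(len(pool)))][::-1],
                _log_uniform(rng, 1e-3, 0.05),
                True,
                frozenset(),
            )
        )
    return SampleResult(
        sample_id=sample_id,
        matches=matches,
        true_species=spec.species,
        true_order=spec.order,
    )


def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[SampleResult], pd.DataFrame, TaxonomyTable, dict[str, list[str]]]:
    """Reproducible cohort: samples, ground-truth table, taxonomy, consensus pools.

    Ovicaprid samples are generated from sheep but carry an unknown true
    species (order Artiodactyla), matching how such samples enter the order
    and human models but not the species model.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    pools = generate_consensus(config, seed=config.seed)
    plan: list[tuple[str, str | None, str]] = []  # (generator species, true species, order)
    for spec in config.species_table:
        for _ in range(spec.n_samples):
            plan.append((spec.species, spec.species, spec.order))
    for _ in range(config.n_ovicaprid):
        plan.append(("Ovis aries", None, "Artiodactyla"))
    samples, truth_rows = [], []
    for i, (gen_species, true_species, order) in enumerate(plan, start=1):
        sid = f"S{i:02d}"
        sample = generate_sample(gen_species, config, rng, sample_id=sid, pools=pools)
        sample.true_species = true_species
        sample.true_order = order
        samples.append(sample)
        truth_rows.append(
            {
                "sample_id": sid,
                "true_species": "" if true_species is None else true_species,
                "true_order": order,
                "generating_species": gen_species,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return samples, truth, config.taxonomy(), pools
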