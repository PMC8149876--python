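"""Taxon attribution counts, ratios and winner calls per sample.

Three datatypes tally the same filtered search results at different levels of
redundancy:

* ``peptide`` — distinct peptide sequences per taxon / total distinct peptides;
* ``psm`` — all match rows (including equal-E alternatives) / total match rows;
* ``spectra`` — distinct spectra per taxon / total distinct spectra, where a
  spectrum is attributed to the union of its peptides' species sets, so an
  isobaric alternative cannot multiply a spectrum's weight.

Because shared peptides are counted once for every species that carries them,
per-taxon ratios can sum to more than 1 across taxa — they are attribution
fractions, not a probability distribution. The "winner" taxon of a sample is
the arg-max of the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .psm_io import HUMAN, SampleResult, SpectrumMatch, TaxonomyTable

__all__ = [
    "WinnerCall",
    "attribute_species",
    "attribute_spectrum",
    "compute_ratios",
    "winner",
    "classify_unique_shared",
    "LEVELS",
    "DATATYPES",
]

LEVELS = ("species", "order", "human")
DATATYPES = ("peptide", "psm", "spectra")

RATIO_COLUMNS = ["sample_id", "level", "taxon", "datatype", "count", "total", "ratio"]


@dataclass(frozen=True)
class WinnerCall:
    sample_id: str
    level: str
    datatype: str
    winner_taxon: str
    winner_ratio: float
    runner_up_taxon: str | None
    runner_up_ratio: float | None
    tie_flag: bool


def attribute_species(
    species: frozenset[str] | set[str], level: str, taxonomy: TaxonomyTable | None
) -> set[str]:
    """Map a species set to taxa at the requested level.

    ``order`` maps through the taxonomy (species with no known order are
    dropped with a warning); ``human`` collapses to a binary human /
    non-human attribution — a set containing Homo sapiens counts as human.
    """
    if level == "species":
        return set(species)
    if level == "order":
        if taxonomy is None:
            raise ValueError("order-level attribution requires a taxonomy")
        orders = set()
        for sp in species:
            o = taxonomy.order_of(sp)
            if o is None:
                warnings.warn(f"species {sp!r} not mapped to an order; dropped")
            else:
                orders.add(o)
        return orders
    if level == "human":
        return {"human"} if HUMAN in species else ({"non-human"} if species else set())
    raise ValueError(f"unknown level {level!r}; expected one of {LEVELS}")


def attribute_spectrum(
    matches_for_one_spectrum: list[SpectrumMatch],
    level: str,
    taxonomy: TaxonomyTable | None = None,
) -> set[str]:
    """Taxa attributed to one spectrum: union over its (equal-E) peptides."""
    ids = {m.spectrum_id for m in matches_for_one_spectrum}
    if len(ids) > 1:
        raise ValueError(f"matches span multiple spectra: {sorted(ids)}")
    species: set[str] = set()
    for m in matches_for_one_spectrum:
        species |= m.species
    return attribute_species(species, level, taxonomy)


def _peptide_species(sample: SampleResult) -> dict[str, set[str]]:
    """Species set per distinct peptide (union across its match rows)."""
    out: dict[str, set[str]] = {}
    for m in sample.target_matches:
        out.setdefault(m.peptide, set()).update(m.species)
    return out


def compute_ratios(
    sample: SampleResult,
    level: str,
    datatype: str,
    taxonomy: TaxonomyTable | None = None,
) -> pd.DataFrame:
    """Per-taxon count / total / ratio rows for one sample and datatype."""
    if datatype not in DATATYPES:
        raise ValueError(f"unknown datatype {datatype!r}; expected one of {DATATYPES}")
    counts: dict[str, int] = {}
    if datatype == "peptide":
        pep_species = _peptide_species(sample)
        total = len(pep_species)
        for species in pep_species.values():
            for taxon in attribute_species(species, level, taxonomy):
                counts[taxon] = counts.get(taxon, 0) + 1
    elif datatype == "psm":
        rows = sample.target_matches
        total = len(rows)
        for m in rows:
            for taxon in attribute_species(m.species, level, taxonomy):
                counts[taxon] = counts.get(taxon, 0) + 1
    else:  # spectra
        groups = sample.spectra()
        total = len(groups)
        for matches in groups.values():
            for taxon in attribute_spectrum(matches, level, taxonomy):
                counts[taxon] = counts.get(taxon, 0) + 1
    if total == 0:
        warnings.warn(f"sample {sample.sample_id}: empty after filtering, no ratios")
        return pd.DataFrame(columns=RATIO_COLUMNS)
    rows = [
        {
            "sample_id": sample.sample_id,
            "level": level,
            "taxon": taxon,
            "datatype": datatype,
            "count": count,
            "total": total,
            "ratio": count / total,
        }
        for taxon, count in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=RATIO_COLUMNS)


def winner(ratios: pd.DataFrame) -> WinnerCall:
    """Arg-max taxon by ratio for one sample/level/datatype; ties flagged.

    Deterministic tie-break: lexicographically smallest taxon name wins, with
    ``tie_flag`` set so the tie is never silent.
    """
    if ratios.empty:
        raise ValueError("winner() requires at least one taxon row")
    for col in ("sample_id", "level", "datatype"):
        if ratios[col].nunique() > 1:
            raise ValueError(f"ratio rows mix several values of {col}")
    ordered = ratios.sort_values(["ratio", "taxon"], ascending=[False, True])
    top = ordered.iloc[0]
    runner = ordered.iloc[1] if len(ordered) > 1 else None
    return WinnerCall(
        sample_id=top["sample_id"],
        level=top["level"],
        datatype=top["datatype"],
        winner_taxon=top["taxon"],
        winner_ratio=float(top["ratio"]),
        runner_up_taxon=None if runner is None else runner["taxon"],
        runner_up_ratio=None if runner is None else float(runner["ratio"]),
        tie_flag=runner is not None and float(runner["ratio"]) == float(top["ratio"]),
    )


def classify_unique_shared(
    sample: SampleResult, taxonomy: TaxonomyTable | None = None
) -> dict:
    """Label each distinct peptide unique-to-one-species or shared.

    Also reports the baseline "unique peptides" winner — the species with the
    most species-unique peptides — which fails whenever a sample has few or no
    peptides unique to its own species.
    """
    pep_species = _peptide_species(sample)
    labels = {
        pep: ("unique" if len(species) == 1 else "shared")
        for pep, species in pep_species.items()
    }
    n = len(labels)
    n_unique = sum(1 for v in labels.values() if v == "unique")
    unique_counts: dict[str, int] = {}
    for pep, species in pep_species.items():
        if len(species) == 1:
            (sp,) = species
            unique_counts[sp] = unique_counts.get(sp, 0) + 1
    unique_winner = (
        min(
            unique_counts,
            key=lambda sp: (-unique_counts[sp], sp),
        )
        if unique_counts
        else None
    )
    return {
        "labels": labels,
        "fraction_unique": n_unique / n if n else 0.0,
        "fraction_shared": (n - n_unique) / n if n else 0.0,
        "unique_counts": unique_counts,
        "unique_peptide_winner": unique_winner,
    }
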