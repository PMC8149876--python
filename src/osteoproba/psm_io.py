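"""Reading, writing and validation of search-result and taxonomy tables.

The canonical interchange format is a tab-separated PSM table with columns
``sample_id, spectrum_id, peptide, e_value, is_decoy, species`` (semicolon
delimited species list) and an optional ``proteins`` column. One row is one
peptide assignment to one spectrum; a spectrum with several equally likely
peptides (identical E-values) occupies several rows that share its
``spectrum_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumMatch",
    "SampleResult",
    "TaxonomyTable",
    "PsmFormatError",
    "PsmValidationError",
    "read_psm_table",
    "write_psm_table",
    "read_taxonomy",
    "write_table",
    "read_table",
    "write_matrix",
    "read_matrix",
]

PSM_COLUMNS = ["sample_id", "spectrum_id", "peptide", "e_value", "is_decoy", "species"]

HUMAN = "homo sapiens"


class PsmFormatError(ValueError):
    """A table is structurally unusable (e.g. a mandatory column is missing)."""


class PsmValidationError(ValueError):
    """A table parsed but violates an invariant (e.g. non-positive E-value)."""


def normalize_species(name: str) -> str:
    """Case-insensitive, whitespace-normalized species key."""
    return " ".join(str(name).split()).lower()


@dataclass(frozen=True)
class SpectrumMatch:
    """One peptide assignment to one spectrum.

    ``species`` holds the normalized names of every species whose database
    proteins contain this peptide; for decoy matches it may be empty.
    """

    sample_id: str
    spectrum_id: str
    peptide: str
    e_value: float
    is_decoy: bool = False
    species: frozenset[str] = field(default_factory=frozenset)
    proteins: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.e_value > 0:
            raise PsmValidationError(
                f"e_value must be > 0, got {self.e_value!r} "
                f"(sample={self.sample_id}, spectrum={self.spectrum_id})"
            )


@dataclass
class SampleResult:
    """All spectrum matches for one bone sample plus its known truth, if any."""

    sample_id: str
    matches: list[SpectrumMatch]
    true_species: str | None = None
    true_order: str | None = None
    database_tag: str = "vertebrate"

    @property
    def target_matches(self) -> list[SpectrumMatch]:
        return [m for m in self.matches if not m.is_decoy]

    @property
    def n_spectra(self) -> int:
        """Distinct target spectra — the sample's total spectrum count."""
        return len({m.spectrum_id for m in self.target_matches})

    @property
    def peptides(self) -> set[str]:
        """Distinct target peptide sequences (modifications included)."""
        return {m.peptide for m in self.target_matches}

    def spectra(self) -> dict[str, list[SpectrumMatch]]:
        """Target matches grouped by spectrum_id (insertion-ordered)."""
        groups: dict[str, list[SpectrumMatch]] = {}
        for m in self.target_matches:
            groups.setdefault(m.spectrum_id, []).append(m)
        return groups

    def with_matches(self, matches: list[SpectrumMatch]) -> "SampleResult":
        return SampleResult(
            sample_id=self.sample_id,
            matches=list(matches),
            true_species=self.true_species,
            true_order=self.true_order,
            database_tag=self.database_tag,
        )


@dataclass
class TaxonomyTable:
    """Species → higher-rank mapping with optional database-entry counts.

    Every species maps to exactly one order; unknown rank cells are stored as
    None. ``db_entries`` mirrors how unevenly species are represented in the
    searched protein database (e.g. 89 entries for white-tailed deer versus
    tens of thousands for sheep).
    """

    frame: pd.DataFrame  # index: normalized species; columns order, class_, db_entries

    @classmethod
    def from_records(
        cls, records: list[tuple], columns: tuple[str, ...] = ("species", "order")
    ) -> "TaxonomyTable":
        df = pd.DataFrame.from_records(list(records), columns=list(columns))
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaxonomyTable":
        df = df.copy()
        if "species" not in df.columns or "order" not in df.columns:
            raise PsmFormatError("taxonomy requires 'species' and 'order' columns")
        df["species"] = df["species"].map(normalize_species)
        df["order"] = df["order"].map(
            lambda v: None if pd.isna(v) or str(v).strip() == "" else str(v).strip()
        )
        dup = df.groupby("species")["order"].nunique(dropna=True)
        conflicts = dup[dup > 1]
        if len(conflicts):
            raise PsmValidationError(
                f"conflicting orders for species: {sorted(conflicts.index)}"
            )
        df = df.drop_duplicates(subset="species", keep="first").set_index("species")
        if "class" in df.columns:
            df = df.rename(columns={"class": "class_"})
        if "db_entries" in df.columns:
            df["db_entries"] = pd.to_numeric(df["db_entries"], errors="coerce")
        return cls(df)

    @property
    def species(self) -> list[str]:
        return list(self.frame.index)

    def order_of(self, species: str) -> str | None:
        key = normalize_species(species)
        if key not in self.frame.index:
            return None
        return self.frame.loc[key, "order"]

    def db_entries_of(self, species: str) -> float | None:
        key = normalize_species(species)
        if "db_entries" not in self.frame.columns or key not in self.frame.index:
            return None
        v = self.frame.loc[key, "db_entries"]
        return None if pd.isna(v) else float(v)


def _split_set(cell) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    text = str(cell).strip()
    if not text:
        return frozenset()
    return frozenset(normalize_species(tok) for tok in text.split(";") if tok.strip())


def _parse_bool(cell) -> bool:
    if isinstance(cell, (bool, np.bool_)):
        return bool(cell)
    return str(cell).strip().lower() in {"1", "true", "t", "yes", "y"}


def read_psm_table(
    path, dialect: str = "tsv", truth: pd.DataFrame | None = None
) -> list[SampleResult]:
    """Read a canonical PSM TSV into one :class:`SampleResult` per sample.

    ``truth`` may carry columns sample_id, true_species, true_order,
    database_tag to annotate samples. Rows sharing (sample, spectrum) but
    differing in peptide are kept as separate matches.
    """
    if dialect != "tsv":
        raise PsmFormatError(f"unsupported dialect {dialect!r}; canonical format is 'tsv'")
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "spectrum_id": str})
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise PsmFormatError(f"PSM table missing mandatory column(s): {missing}")
    return psm_frame_to_samples(df, truth=truth)


def psm_frame_to_samples(
    df: pd.DataFrame, truth: pd.DataFrame | None = None
) -> list[SampleResult]:
    truth_map: dict[str, dict] = {}
    if truth is not None:
        for _, row in truth.iterrows():
            truth_map[str(row["sample_id"])] = row.to_dict()
    samples = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        matches = []
        for _, row in grp.iterrows():
            e_value = float(row["e_value"])
            if not e_value > 0:
                raise PsmValidationError(
                    f"non-positive e_value {e_value!r} in sample {sample_id}, "
                    f"spectrum {row['spectrum_id']}"
                )
            matches.append(
                SpectrumMatch(
                    sample_id=str(sample_id),
                    spectrum_id=str(row["spectrum_id"]),
                    peptide=str(row["peptide"]),
                    e_value=e_value,
                    is_decoy=_parse_bool(row["is_decoy"]),
                    species=_split_set(row.get("species")),
                    proteins=_split_set(row.get("proteins")),
                )
            )
        info = truth_map.get(str(sample_id), {})
        samples.append(
            SampleResult(
                sample_id=str(sample_id),
                matches=matches,
                true_species=info.get("true_species"),
                true_order=info.get("true_order"),
                database_tag=info.get("database_tag", "vertebrate"),
            )
        )
    return samples


def samples_to_frame(samples: list[SampleResult]) -> pd.DataFrame:
    rows = []
    for s in samples:
        for m in s.matches:
            rows.append(
                {
                    "sample_id": m.sample_id,
                    "spectrum_id": m.spectrum_id,
                    "peptide": m.peptide,
                    "e_value": m.e_value,
                    "is_decoy": m.is_decoy,
                    "species": ";".join(sorted(m.species)),
                    "proteins": ";".join(sorted(m.proteins)),
                }
            )
    return pd.DataFrame(rows, columns=PSM_COLUMNS + ["proteins"])


def write_psm_table(samples: list[SampleResult], path) -> None:
    samples_to_frame(samples).to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t")
    return TaxonomyTable.from_frame(df)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    out = tax.frame.reset_index().rename(columns={"class_": "class"})
    out.to_csv(path, sep="\t", index=False)


def write_table(obj, path) -> None:
    """Write any tabular artifact (DataFrame) as TSV with header."""
    if not isinstance(obj, pd.DataFrame):
        obj = pd.DataFrame(obj)
    obj.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrix(matrix: np.ndarray, labels: list[str], path) -> None:
    """Labeled square matrix as TSV (row index + header)."""
    pd.DataFrame(np.asarray(matrix), index=labels, columns=labels).to_csv(path, sep="\t")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def convert_xtandem_xml(path, sample_id: str | None = None):  # pragma: no cover - stub
    """Converter stub for X! Tandem output XML.

    The canonical pipeline consumes the TSV interchange format; X! Tandem XML
    layouts are version-bound, so conversion is left to ``pyteomics.tandem``
    downstream of this stub. Each peptide-protein assignment is interpreted as
    one species attribution row (one row per protein, aggregated to a species
    set per spectrum).
    """
    from pyteomics import tandem  # noqa: F401

    raise NotImplementedError(
        "X! Tandem XML conversion is a stub; export your search results to the "
        "canonical PSM TSV (see module docstring) instead."
    )
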