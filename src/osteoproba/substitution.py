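"""Classification of wrong-species peptides against a reference consensus.

Collagen peptides attributed to a species other than the sample's typically
differ from the true species' peptide by a single amino acid. Such variants
fall into two groups:

* **isobaric** — indistinguishable by mass from the reference: an isobaric
  residue swap (I ⇔ L), a modification-compensated pair such as
  hydroxyproline+Ala ⇔ Pro+Ser, or an adjacent / near-adjacent inversion with
  no distinguishing fragment ions (~PGS~ ⇔ ~SGP~);
* **non-isobaric** — a mass-changing substitution, further stratified by the
  minimal number of nucleotide changes needed to explain it under the standard
  genetic code (single-nucleotide changes are biologically far more plausible
  than multi-nucleotide or multi-residue changes).

Modifications are written inline as residue followed by a bracketed delta or
name, e.g. ``P[+15.9949]`` or ``P[OH]`` for hydroxyproline.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from pyteomics import mass as pmass
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "SubstitutionCall",
    "parse_peptide",
    "strip_modifications",
    "peptide_mass",
    "pick_reference",
    "classify",
    "min_nt_changes",
    "stratify_evalues",
    "GROUPS",
]

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")

# supported modification names -> monoisotopic mass delta (Da)
MOD_DELTAS = {"OH": 15.9949, "OX": 15.9949}

DEFAULT_TOLERANCE = 0.02  # Da; strict chemical isobarity (excludes K/Q at 0.036)
INVERSION_WINDOW = 3  # "adjacent or near adjacent" inversions

_TOKEN = re.compile(r"([A-Z])(\[([^\]]+)\])?")


def parse_peptide(peptide: str) -> list[tuple[str, float]]:
    """Split a peptide string into (residue, modification delta) tokens."""
    pos = 0
    tokens: list[tuple[str, float]] = []
    for m in _TOKEN.finditer(peptide):
        if m.start() != pos:
            raise ValueError(f"unparseable peptide {peptide!r} at position {pos}")
        pos = m.end()
        aa = m.group(1)
        if aa not in AA_LETTERS:
            raise ValueError(f"unknown residue {aa!r} in peptide {peptide!r}")
        delta = 0.0
        if m.group(3) is not None:
            token = m.group(3).strip()
            if token.upper() in MOD_DELTAS:
                delta = MOD_DELTAS[token.upper()]
            else:
                try:
                    delta = float(token)
                except ValueError:
                    raise ValueError(
                        f"unsupported modification {token!r} in peptide {peptide!r}"
                    ) from None
        tokens.append((aa, delta))
    if pos != len(peptide) or not tokens:
        raise ValueError(f"unparseable peptide {peptide!r}")
    return tokens


def strip_modifications(peptide: str) -> str:
    return "".join(aa for aa, _ in parse_peptide(peptide))


def _residue_mass(aa: str, delta: float) -> float:
    return pmass.std_aa_mass[aa] + delta


def peptide_mass(peptide: str) -> float:
    """Monoisotopic peptide mass including inline modifications."""
    tokens = parse_peptide(peptide)
    water = pmass.calculate_mass(formula="H2O")
    return water + sum(_residue_mass(aa, d) for aa, d in tokens)


# ---------------------------------------------------------------------------
# minimal nucleotide distance between amino acids (standard genetic code)

def _codon_tables() -> dict[str, list[str]]:
    table = CodonTable.standard_dna_table.forward_table
    codons: dict[str, list[str]] = {}
    for codon, aa in table.items():
        codons.setdefault(aa, []).append(codon)
    return codons


_CODONS = _codon_tables()


def min_nt_changes(aa_from: str, aa_to: str) -> int:
    """Minimum Hamming distance over all codon pairs encoding the two residues."""
    for aa in (aa_from, aa_to):
        if aa not in _CODONS:
            raise ValueError(f"not a standard coding amino acid: {aa!r}")
    return min(
        sum(a != b for a, b in zip(c1, c2))
        for c1, c2 in itertools.product(_CODONS[aa_from], _CODONS[aa_to])
    )


# ---------------------------------------------------------------------------
# classification

@dataclass(frozen=True)
class SubstitutionCall:
    peptide: str
    reference_peptide: str
    klass: str  # correct | isobaric | non_isobaric
    n_aa_changes: int
    min_nt_changes: int | None = None
    mechanisms: frozenset[str] = field(default_factory=frozenset)
    e_value: float | None = None


def pick_reference(peptide: str, consensus: set[str] | list[str]) -> str | None:
    """Closest equal-length consensus peptide by Hamming distance, or None.

    Lengths and positions are compared on modification-stripped sequences;
    ties break deterministically to the lexicographically smallest reference.
    """
    bare = strip_modifications(peptide)
    best: tuple[int, str] | None = None
    for cand in sorted(set(consensus)):
        cbare = strip_modifications(cand)
        if len(cbare) != len(bare):
            continue
        d = sum(a != b for a, b in zip(bare, cbare))
        if best is None or d < best[0]:
            best = (d, cand)
    return None if best is None else best[1]


def _window_span(positions: list[int]) -> int:
    return positions[-1] - positions[0] + 1


def _diff_positions(tok_a, tok_b, with_mods: bool) -> list[int]:
    out = []
    for i, ((aa1, d1), (aa2, d2)) in enumerate(zip(tok_a, tok_b)):
        if aa1 != aa2 or (with_mods and abs(d1 - d2) > 1e-9):
            out.append(i)
    return out


def classify(
    peptide: str,
    reference: str,
    tolerance: float = DEFAULT_TOLERANCE,
    e_value: float | None = None,
) -> SubstitutionCall:
    """Classify a peptide against an equal-length reference.

    Positional (amino-acid) changes are counted on modification-stripped
    sequences; isobarity uses full masses including modifications. A call is
    isobaric only when the total masses agree within ``tolerance`` AND a
    concrete mechanism is identifiable — residue swap, modification-
    compensated pair, or local inversion. Everything else with >= 1 residue
    change is non-isobaric, with the summed minimal nucleotide distance.
    """
    tok_p = parse_peptide(peptide)
    tok_r = parse_peptide(reference)
    if len(tok_p) != len(tok_r):
        raise ValueError("classify() requires equal-length peptides")

    aa_changes = _diff_positions(tok_p, tok_r, with_mods=False)
    n_aa = len(aa_changes)
    if n_aa == 0:
        return SubstitutionCall(peptide, reference, "correct", 0, 0, frozenset(), e_value)

    mass_equal = abs(peptide_mass(peptide) - peptide_mass(reference)) <= tolerance
    mechanisms: set[str] = set()
    if mass_equal:
        # residue swap: every changed position swaps to an equal-mass residue
        if all(
            abs(_residue_mass(*tok_p[i]) - _residue_mass(*tok_r[i])) <= tolerance
            for i in aa_changes
        ):
            mechanisms.add("residue_swap")
        # any position where residue or modification differs
        full_changes = _diff_positions(tok_p, tok_r, with_mods=True)
        if full_changes and _window_span(full_changes) <= INVERSION_WINDOW:
            lo, hi = full_changes[0], full_changes[-1] + 1
            mass_p = sum(_residue_mass(*t) for t in tok_p[lo:hi])
            mass_r = sum(_residue_mass(*t) for t in tok_r[lo:hi])
            has_mod = any(d != 0 for _, d in tok_p[lo:hi] + tok_r[lo:hi])
            if has_mod and abs(mass_p - mass_r) <= tolerance:
                mechanisms.add("modification_pair")
            bag_p = sorted(aa for aa, _ in tok_p[lo:hi])
            bag_r = sorted(aa for aa, _ in tok_r[lo:hi])
            if bag_p == bag_r:
                mechanisms.add("inversion")
    if mass_equal and mechanisms:
        return SubstitutionCall(
            peptide, reference, "isobaric", n_aa, None, frozenset(mechanisms), e_value
        )
    nt = sum(min_nt_changes(tok_r[i][0], tok_p[i][0]) for i in aa_changes)
    return SubstitutionCall(
        peptide, reference, "non_isobaric", n_aa, nt, frozenset(), e_value
    )


# ---------------------------------------------------------------------------
# E-value stratification (ANOVA + Tukey HSD on log10 E)

GROUPS = ("correct", "isobaric", "non_isobaric_1aa", "non_isobaric_multi_aa")


def group_of(call: SubstitutionCall) -> str:
    if call.klass == "correct":
        return "correct"
    if call.klass == "isobaric":
        return "isobaric"
    return "non_isobaric_1aa" if call.n_aa_changes == 1 else "non_isobaric_multi_aa"


def stratify_evalues(calls: list[SubstitutionCall], alpha: float = 0.01) -> dict:
    """Summaries and pairwise tests of E-values across substitution classes.

    E-values span orders of magnitude, so the one-way ANOVA and the post-hoc
    Tukey HSD run on log10(E). Groups with fewer than two observations are
    summarized but excluded from testing.
    """
    rows = [
        {"group": group_of(c), "e_value": c.e_value}
        for c in calls
        if c.e_value is not None
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no calls carry E-values")
    summary = (
        df.groupby("group")["e_value"]
        .agg(n="count", median="median", q1=lambda s: s.quantile(0.25),
             q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    testable = [g for g, sub in df.groupby("group") if len(sub) >= 2]
    excluded = sorted(set(df["group"]) - set(testable))
    result = {"summary": summary, "excluded_groups": excluded, "anova_p": None,
              "tukey": None, "different_pairs": []}
    if len(testable) < 2:
        return result
    sub = df[df["group"].isin(testable)]
    logs = [np.log10(g["e_value"].to_numpy()) for _, g in sub.groupby("group")]
    result["anova_p"] = float(stats.f_oneway(*logs).pvalue)
    tuk = pairwise_tukeyhsd(
        np.log10(sub["e_value"].to_numpy()), sub["group"].to_numpy(), alpha=alpha
    )
    tukey_df = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
    result["tukey"] = tukey_df
    result["different_pairs"] = [
        (str(r["group1"]), str(r["group2"]))
        for _, r in tukey_df.iterrows()
        if bool(r["reject"])
    ]
    return result


def calls_to_frame(calls: list[SubstitutionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "peptide": c.peptide,
                "reference_peptide": c.reference_peptide,
                "class": c.klass,
                "n_aa_changes": c.n_aa_changes,
                "min_nt_changes": c.min_nt_changes,
                "mechanisms": ";".join(sorted(c.mechanisms)),
                "e_value": c.e_value,
            }
            for c in calls
        ]
    )


def classify_sample_peptides(
    wrong_peptides: list[tuple[str, float]],
    consensus: set[str],
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[list[SubstitutionCall], list[str]]:
    """Classify (peptide, e_value) pairs against a species consensus set.

    Peptides with no equal-length consensus counterpart cannot be classified
    and are returned separately.
    """
    calls, unmatched = [], []
    for pep, e in wrong_peptides:
        ref = pick_reference(pep, consensus)
        if ref is None:
            unmatched.append(pep)
            continue
        calls.append(classify(pep, ref, tolerance=tolerance, e_value=e))
    if unmatched:
        warnings.warn(f"{len(unmatched)} peptide(s) had no equal-length reference")
    return calls, unmatched
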