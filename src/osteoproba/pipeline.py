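"""End-to-end orchestration: filter -> tally -> winners -> model inputs.

These helpers chain the per-module operations over a whole cohort and are the
workhorses behind the CLI, the examples and the acceptance checks.
"""

from __future__ import annotations

import warnings

import pandas as pd

from . import bayes, filtering, tally
from .psm_io import SampleResult, TaxonomyTable, normalize_species

__all__ = [
    "filter_cohort",
    "ratio_table",
    "winner_table",
    "winner_accuracy",
    "human_ratio",
    "build_model_input",
]


def filter_cohort(
    samples: list[SampleResult],
    fdr_max: float = filtering.DEFAULT_FDR_MAX,
    e_cap: float = filtering.DEFAULT_E_CAP,
) -> tuple[list[SampleResult], pd.DataFrame]:
    """FDR-filter every sample; returns filtered samples + per-sample report."""
    filtered, rows = [], []
    for sample in samples:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fs, res = filtering.filter_sample(sample, fdr_max=fdr_max, e_cap=e_cap)
        filtered.append(fs)
        rows.append(
            {
                "sample_id": res.sample_id,
                "chosen_e_threshold": res.chosen_e_threshold,
                "fdr_at_threshold": res.fdr_at_threshold,
                "n_target_kept": res.n_target_kept,
                "n_decoy_kept": res.n_decoy_kept,
                "empty": res.empty,
            }
        )
    return filtered, pd.DataFrame(rows)


def ratio_table(
    samples: list[SampleResult],
    level: str,
    datatype: str,
    taxonomy: TaxonomyTable | None = None,
) -> pd.DataFrame:
    """Concatenated per-taxon ratio rows for a whole cohort."""
    frames = []
    for sample in samples:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frames.append(tally.compute_ratios(sample, level, datatype, taxonomy))
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=tally.RATIO_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def winner_table(ratios: pd.DataFrame) -> list[tally.WinnerCall]:
    calls = []
    for _, grp in ratios.groupby("sample_id", sort=True):
        calls.append(tally.winner(grp))
    return calls


def winner_accuracy(
    calls: list[tally.WinnerCall], truth: dict[str, dict], level: str = "species"
) -> float:
    """Fraction of known-truth samples whose winner matches the truth."""
    key = "true_species" if level == "species" else "true_order"
    hits = total = 0
    for call in calls:
        true_val = truth.get(call.sample_id, {}).get(key)
        if true_val is None or str(true_val).strip() == "":
            continue
        total += 1
        hits += int(normalize_species(call.winner_taxon) == normalize_species(true_val))
    if total == 0:
        raise ValueError("no samples with known truth at this level")
    return hits / total


def human_ratio(ratios_human_level: pd.DataFrame) -> dict[str, float]:
    """Per-sample ratio attributed to the 'human' taxon (0 when absent)."""
    out: dict[str, float] = {}
    for sid, grp in ratios_human_level.groupby("sample_id", sort=True):
        row = grp[grp["taxon"] == "human"]
        out[str(sid)] = float(row["ratio"].iloc[0]) if len(row) else 0.0
    return out


def build_model_input(
    samples: list[SampleResult],
    truth: pd.DataFrame,
    taxonomy: TaxonomyTable,
    model_tag: str,
    datatype: str = "spectra",
) -> bayes.ModelInput:
    """Tally a filtered cohort and assemble one Bayesian model's input rows."""
    truth_map = {str(r["sample_id"]): r.to_dict() for _, r in truth.iterrows()}
    if model_tag == "human":
        ratios = ratio_table(samples, "human", datatype, taxonomy)
        hr = human_ratio(ratios)
        calls = winner_table(ratios)
        return bayes.model_input_from_winners(
            calls, truth_map, "human", datatype, human_ratios=hr
        )
    level = "species" if model_tag == "species" else "order"
    ratios = ratio_table(samples, level, datatype, taxonomy)
    calls = winner_table(ratios)
    return bayes.model_input_from_winners(calls, truth_map, model_tag, datatype)
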