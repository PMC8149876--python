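"""Per-sample decoy-based FDR estimation and E-value filtering.

The false discovery rate at a candidate E-value threshold is the number of
non-redundant (distinct peptide sequence) decoy PSMs at or below the threshold
divided by the number of non-redundant target PSMs at or below it. Each sample
is filtered at the largest observed E-value that keeps FDR < 1%, capped
unconditionally at E = 0.01 — the cap matters because many bone samples yield
no decoy hits at all, which would otherwise leave the threshold unbounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .psm_io import SampleResult

__all__ = ["FdrResult", "estimate_fdr", "choose_threshold", "apply_filter", "filter_sample"]

DEFAULT_FDR_MAX = 0.01
DEFAULT_E_CAP = 0.01


@dataclass(frozen=True)
class FdrResult:
    sample_id: str
    chosen_e_threshold: float
    fdr_at_threshold: float
    n_target_kept: int
    n_decoy_kept: int
    empty: bool = False


def _nonredundant_counts(sample: SampleResult, e_threshold: float) -> tuple[int, int]:
    """(distinct decoy peptides, distinct target peptides) at e <= threshold."""
    decoys = {m.peptide for m in sample.matches if m.is_decoy and m.e_value <= e_threshold}
    targets = {m.peptide for m in sample.matches if not m.is_decoy and m.e_value <= e_threshold}
    return len(decoys), len(targets)


def estimate_fdr(sample: SampleResult, e_threshold: float) -> float:
    """FDR = non-redundant decoys / non-redundant targets at ``e_threshold``.

    Returns 0 when no decoys pass; also 0 (with a warning) when no targets
    pass, in which case the ratio is undefined.
    """
    n_decoy, n_target = _nonredundant_counts(sample, e_threshold)
    if n_target == 0:
        if n_decoy:
            warnings.warn(
                f"sample {sample.sample_id}: decoys but no targets at "
                f"E <= {e_threshold}; FDR undefined, reported as 0"
            )
        return 0.0
    return n_decoy / n_target


def choose_threshold(
    sample: SampleResult,
    fdr_max: float = DEFAULT_FDR_MAX,
    e_cap: float = DEFAULT_E_CAP,
) -> FdrResult:
    """Select the largest observed target E-value <= ``e_cap`` with FDR < ``fdr_max``.

    Candidate thresholds are the observed target E-values (a step function —
    FDR only changes there). With no decoys the threshold is the cap itself.
    """
    target_es = sorted(
        {m.e_value for m in sample.matches if not m.is_decoy and m.e_value <= e_cap}
    )
    if target_es:
        # the cap itself is always a candidate (reported when FDR allows it)
        target_es = sorted(set(target_es) | {e_cap})
    if not target_es:
        warnings.warn(f"sample {sample.sample_id}: no target matches at E <= {e_cap}")
        return FdrResult(sample.sample_id, e_cap, 0.0, 0, 0, empty=True)

    has_decoys = any(m.is_decoy and m.e_value <= e_cap for m in sample.matches)
    if not has_decoys:
        n_decoy, n_target = _nonredundant_counts(sample, e_cap)
        return FdrResult(sample.sample_id, e_cap, 0.0, n_target, n_decoy)

    chosen = None
    for t in reversed(target_es):
        if estimate_fdr(sample, t) < fdr_max:
            chosen = t
            break
    if chosen is None:
        # even the strictest observed threshold fails; keep it, flag via warning
        chosen = target_es[0]
        warnings.warn(
            f"sample {sample.sample_id}: no threshold achieves FDR < {fdr_max}; "
            f"using strictest observed E-value {chosen}"
        )
    # the cap may be looser than the chosen observed E-value but never tighter
    chosen = min(chosen, e_cap)
    n_decoy, n_target = _nonredundant_counts(sample, chosen)
    return FdrResult(
        sample.sample_id, chosen, estimate_fdr(sample, chosen), n_target, n_decoy
    )


def apply_filter(sample: SampleResult, fdr_result: FdrResult) -> SampleResult:
    """Keep target matches with E <= threshold; decoys are dropped entirely.

    Equal-E-value alternative peptides of one spectrum pass or fail together
    because they share one E-value.
    """
    kept = [
        m
        for m in sample.matches
        if not m.is_decoy and m.e_value <= fdr_result.chosen_e_threshold
    ]
    if not kept:
        warnings.warn(f"sample {sample.sample_id}: no matches pass the E-value filter")
    return sample.with_matches(kept)


def filter_sample(
    sample: SampleResult,
    fdr_max: float = DEFAULT_FDR_MAX,
    e_cap: float = DEFAULT_E_CAP,
) -> tuple[SampleResult, FdrResult]:
    """Convenience: choose a threshold and apply it."""
    res = choose_threshold(sample, fdr_max=fdr_max, e_cap=e_cap)
    return apply_filter(sample, res), res
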