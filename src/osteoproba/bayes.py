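"""Bayesian logistic regression of identification correctness on winner ratio.

Three binary models share one structure: the probability that a sample's top
("winner") taxon is correct is modelled as

    p(ratio) = logit^-1(alpha + beta * ratio)

where ratio is the sample's winner ratio (species and order models) or its
human spectra ratio (human model), and the label is 1 when the winner matches
the known truth. Weakly informative Normal(0, 10^2) priors on alpha and beta
regularize the posterior under complete separation, which is the expected
regime for the order and human models.

Posterior sampling uses the affine-invariant ensemble sampler (emcee); the
walker ensemble is exposed to ArviZ as chains for split-R-hat / ESS
diagnostics and for PSIS-LOO model comparison on the deviance scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

__all__ = [
    "ModelInput",
    "PriorSpec",
    "SamplerSettings",
    "LogisticFit",
    "fit",
    "predict_prob",
    "probability_curve",
    "exact_loo",
    "roc_auc",
    "psis_loo_compare",
    "model_input_from_winners",
]

MODEL_TAGS = ("species", "order", "human")


@dataclass
class ModelInput:
    """Per-sample (ratio, label) rows for one model and datatype."""

    sample_ids: list[str]
    ratios: np.ndarray
    labels: np.ndarray
    model_tag: str = "species"
    datatype: str = "spectra"

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.ratios.shape != self.labels.shape or self.ratios.ndim != 1:
            raise ValueError("ratios and labels must be equal-length 1-D arrays")
        if np.any((self.ratios < 0) | (self.ratios > 1)):
            raise ValueError("ratios must lie in [0, 1]")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.ratios)

    def drop(self, index: int) -> "ModelInput":
        keep = np.arange(len(self)) != index
        return ModelInput(
            [sid for k, sid in zip(keep, self.sample_ids) if k],
            self.ratios[keep],
            self.labels[keep],
            self.model_tag,
            self.datatype,
        )


@dataclass(frozen=True)
class PriorSpec:
    alpha_sd: float = 10.0
    beta_sd: float = 10.0


@dataclass(frozen=True)
class SamplerSettings:
    """Ensemble-sampler configuration: walkers play the role of chains."""

    n_walkers: int = 16
    n_draws: int = 2000  # post-warmup steps per walker
    n_warmup: int = 1000
    seed: int = 0


@dataclass
class LogisticFit:
    """Posterior draws of (alpha, beta) plus diagnostics and metadata."""

    alpha: np.ndarray  # (chain, draw)
    beta: np.ndarray  # (chain, draw)
    inputs: ModelInput
    priors: PriorSpec
    settings: SamplerSettings
    diagnostics: dict = field(default_factory=dict)

    @property
    def alpha_flat(self) -> np.ndarray:
        return self.alpha.reshape(-1)

    @property
    def beta_flat(self) -> np.ndarray:
        return self.beta.reshape(-1)

    def to_inference_data(self) -> az.InferenceData:
        loglik = _pointwise_loglik(
            self.alpha[..., None], self.beta[..., None],
            self.inputs.ratios, self.inputs.labels,
        )
        return az.from_dict(
            posterior={"alpha": self.alpha, "beta": self.beta},
            log_likelihood={"y": loglik},
            coords={"obs_id": self.inputs.sample_ids},
            dims={"y": ["obs_id"]},
        )

    def summary(self) -> pd.DataFrame:
        return az.summary(
            az.from_dict(posterior={"alpha": self.alpha, "beta": self.beta})
        )


def _pointwise_loglik(alpha, beta, ratios, labels) -> np.ndarray:
    """Bernoulli log-likelihood per draw and observation (broadcasting)."""
    eta = alpha + beta * ratios
    # log p(y|eta): log_expit(eta) for y=1, log_expit(-eta) for y=0
    return np.where(labels == 1, log_expit(eta), log_expit(-eta))


def _log_posterior(theta, ratios, labels, priors: PriorSpec) -> float:
    alpha, beta = theta
    lp = -0.5 * (alpha / priors.alpha_sd) ** 2 - 0.5 * (beta / priors.beta_sd) ** 2
    eta = alpha + beta * ratios
    return lp + float(np.sum(np.where(labels == 1, log_expit(eta), log_expit(-eta))))


def fit(
    inputs: ModelInput,
    priors: PriorSpec | None = None,
    settings: SamplerSettings | None = None,
) -> LogisticFit:
    """Sample the posterior of (alpha, beta); reproducible given the seed.

    Complete separation and even all-one-label inputs are handled by the
    priors; the latter produces a warning and wide posteriors, not a crash.
    """
    priors = priors or PriorSpec()
    settings = settings or SamplerSettings()
    if len(inputs) < 2:
        raise ValueError("need at least two samples to fit")
    if len(np.unique(inputs.labels)) < 2:
        warnings.warn(
            f"model {inputs.model_tag}: all labels identical; posterior driven by priors"
        )
    rng = np.random.default_rng(settings.seed)
    p0 = rng.normal(scale=1.0, size=(settings.n_walkers, 2))
    sampler = emcee.EnsembleSampler(
        settings.n_walkers,
        2,
        _log_posterior,
        args=(inputs.ratios, inputs.labels, priors),
        # differential-evolution moves mix far better than the default
        # stretch move on the strongly correlated (alpha, beta) posterior
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler.random_state = np.random.RandomState(settings.seed).get_state()
    state = sampler.run_mcmc(p0, settings.n_warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, settings.n_draws, progress=False)
    chain = sampler.get_chain()  # (draw, walker, 2)
    alpha = chain[:, :, 0].T.copy()  # (chain, draw)
    beta = chain[:, :, 1].T.copy()
    out = LogisticFit(alpha, beta, inputs, priors, settings)
    idata = az.from_dict(posterior={"alpha": alpha, "beta": beta})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    out.diagnostics = {
        "rhat_alpha": float(rhat["alpha"].values),
        "rhat_beta": float(rhat["beta"].values),
        "ess_alpha": float(ess["alpha"].values),
        "ess_beta": float(ess["beta"].values),
        "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
    }
    if max(out.diagnostics["rhat_alpha"], out.diagnostics["rhat_beta"]) > 1.01:
        warnings.warn(
            f"model {inputs.model_tag}: R-hat exceeds 1.01 "
            f"({out.diagnostics['rhat_alpha']:.3f}, {out.diagnostics['rhat_beta']:.3f})"
        )
    return out


def predict_prob(fit_: LogisticFit, ratio: float) -> dict:
    """Posterior of p at one ratio: draws, mean, central 95% interval."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio must lie in [0, 1], got {ratio}")
    draws = expit(fit_.alpha_flat + fit_.beta_flat * ratio)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {"draws": draws, "mean": float(draws.mean()), "lower": float(lo), "upper": float(hi)}


def probability_curve(fit_: LogisticFit, grid_size: int = 101) -> pd.DataFrame:
    """Mean posterior p and central 95% band over a uniform ratio grid."""
    grid = np.linspace(0.0, 1.0, grid_size)
    draws = expit(
        fit_.alpha_flat[None, :] + np.outer(grid, fit_.beta_flat)
    )  # (grid, draws)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=1)
    return pd.DataFrame(
        {"ratio": grid, "mean_p": draws.mean(axis=1), "lower": lo, "upper": hi}
    )


def exact_loo(
    inputs: ModelInput,
    priors: PriorSpec | None = None,
    settings: SamplerSettings | None = None,
) -> pd.DataFrame:
    """Exact leave-one-out: refit without each sample, predict it unseen.

    Returns one row per sample with the held-out posterior predictive mean of
    its correctness probability and a central 95% interval. A refit whose
    R-hat misses the 1.01 target is flagged in the ``converged`` column.
    """
    if len(inputs) < 3:
        raise ValueError("exact LOO requires at least three samples")
    settings = settings or SamplerSettings()
    rows = []
    for i in range(len(inputs)):
        sub = inputs.drop(i)
        refit_settings = replace(settings, seed=settings.seed + i)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = fit(sub, priors=priors, settings=refit_settings)
        pred = predict_prob(f, float(inputs.ratios[i]))
        converged = max(f.diagnostics["rhat_alpha"], f.diagnostics["rhat_beta"]) <= 1.05
        if not converged:
            warnings.warn(
                f"LOO refit excluding {inputs.sample_ids[i]} did not converge; flagged"
            )
        rows.append(
            {
                "sample_id": inputs.sample_ids[i],
                "ratio": float(inputs.ratios[i]),
                "label": int(inputs.labels[i]),
                "mean_p": pred["mean"],
                "lower": pred["lower"],
                "upper": pred["upper"],
                "converged": converged,
            }
        )
    return pd.DataFrame(rows)


def roc_auc(predictions, labels) -> dict:
    """Empirical ROC over thresholds on the means; trapezoidal AUC.

    Tied predictions are traversed together (rank-averaged), which makes the
    trapezoidal area equal to the Mann-Whitney U statistic / (n1 * n0).
    """
    from sklearn.metrics import roc_curve, auc as sk_auc

    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = set(np.unique(labels))
    if classes != {0, 1}:
        raise ValueError(f"both labels must be present; got {sorted(classes)}")
    fpr, tpr, thresholds = roc_curve(labels, predictions)
    return {"fpr": fpr, "tpr": tpr, "thresholds": thresholds, "auc": float(sk_auc(fpr, tpr))}


def psis_loo_compare(fits: dict[str, LogisticFit]) -> pd.DataFrame:
    """PSIS-LOO comparison of fits on the same samples, deviance scale.

    Returns the ArviZ comparison table (best model first) augmented with a
    ``pareto_k_warning`` column; a high Pareto-k fraction means the importance
    sampling approximation is unreliable and exact LOO should be preferred.
    """
    ids = {name: tuple(f.inputs.sample_ids) for name, f in fits.items()}
    if len(set(ids.values())) != 1:
        raise ValueError("all fits must cover the same samples for comparison")
    idatas = {name: f.to_inference_data() for name, f in fits.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comp = az.compare(idatas, ic="loo", scale="deviance")
        k_warn = {}
        for name, idata in idatas.items():
            loo = az.loo(idata, pointwise=True)
            frac = float(np.mean(loo.pareto_k.values > 0.7))
            k_warn[name] = frac
            if frac > 0.0:
                warnings.warn(
                    f"model {name}: {frac:.0%} of Pareto-k values exceed 0.7; "
                    "consider exact LOO",
                    stacklevel=2,
                )
    comp = comp.copy()
    comp["pareto_k_warning"] = [k_warn[n] for n in comp.index]
    return comp


def model_input_from_winners(
    winner_calls: list,
    truth: dict[str, dict],
    model_tag: str,
    datatype: str = "spectra",
    human_ratios: dict[str, float] | None = None,
) -> ModelInput:
    """Assemble (ratio, label) rows from winner calls and known ground truth.

    Species model: label 1 iff winner species == true species; samples with
    unknown species (e.g. ovicaprids) are excluded. Order model: winner order
    vs true order, all samples kept. Human model: the covariate is the human
    spectra ratio itself and the label marks known human samples.
    """
    from .psm_io import normalize_species

    ids, ratios, labels = [], [], []
    for call in winner_calls:
        info = truth.get(call.sample_id, {})
        if model_tag == "species":
            true_sp = info.get("true_species")
            if true_sp is None or str(true_sp).strip() == "":
                continue
            label = int(normalize_species(call.winner_taxon) == normalize_species(true_sp))
            ratio = call.winner_ratio
        elif model_tag == "order":
            true_ord = info.get("true_order")
            if true_ord is None or str(true_ord).strip() == "":
                continue
            label = int(str(call.winner_taxon).strip().lower() == str(true_ord).strip().lower())
            ratio = call.winner_ratio
        elif model_tag == "human":
            true_sp = info.get("true_species")
            label = int(
                true_sp is not None and normalize_species(true_sp) == "homo sapiens"
            )
            if human_ratios is None:
                raise ValueError("human model requires per-sample human ratios")
            ratio = human_ratios.get(call.sample_id, 0.0)
        else:
            raise ValueError(f"unknown model tag {model_tag!r}")
        ids.append(call.sample_id)
        ratios.append(ratio)
        labels.append(label)
    return ModelInput(ids, np.array(ratios), np.array(labels), model_tag, datatype)
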