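"""Ensemble orchestration: sampling quotas, medians, condition comparison.

The central objects follow the model/results convention: an
:class:`EnsembleModel` is built from a metabolic model, one condition's
processed dataset and a standard-Gibbs table; ``fit()`` repeats sampling
attempts (each with a seed derived from the base seed, the condition label
and the attempt index, so attempt streams are auditable and independent of
acceptance history) until the retention quota is met — executing at least
``min_attempts`` attempts — filters by linear stability, computes the flux
control coefficient matrix of every retained instance, and returns an
:class:`EnsembleResult`.

Cross-condition operations (median tables for heat maps, two-sample
Kolmogorov-Smirnov comparison of coefficient distributions, convergence of
running medians) are module functions over Results objects.
"""

from __future__ import annotations

import json
import warnings
import zlib
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ConditionDataset
from .mca import ControlCoefficientMatrix, flux_control_coefficients
from .model import MetabolicModel
from .sampler import KineticInstance, KineticSolveError, sample_instance
from .stability import JacobianReport, jacobian_at_reference
from .thermo import StandardGibbs, ThermoConfig, ThermoInfeasible

__all__ = [
    "PipelineConfig",
    "EnsembleModel",
    "EnsembleResult",
    "run_condition",
    "median_control_table",
    "ks_compare",
    "ks_table",
    "convergence_curve",
    "attempt_rng",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Sampling-campaign configuration.

    ``n_target`` retained instances per condition (quota); at least
    ``min_attempts`` sampling attempts are executed even when the quota is
    met earlier (surplus acceptances are logged, not retained).
    """

    n_target: int = 100
    min_attempts: int = 120
    stability_threshold: float = 1e-5
    base_seed: int = 0
    fd_delta: float = 1e-6
    filter_unstable: bool = True
    attempt_cap: int = 20000
    acceptance_floor: float = 0.005
    temperature: float = 303.15

    def __post_init__(self) -> None:
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")

    @property
    def thermo(self) -> ThermoConfig:
        return ThermoConfig(T=self.temperature)


def attempt_rng(base_seed: int, condition: str, attempt: int) -> np.random.Generator:
    """Deterministic per-attempt generator.

    Seeded from (base seed, CRC32 of the condition label, attempt index),
    so the stream of attempt k does not depend on the outcomes of attempts
    0..k-1 and attempt counts are auditable.
    """
    label_key = zlib.crc32(condition.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([base_seed, label_key, attempt]))


@dataclass
class EnsembleResult:
    """Retained ensemble of one condition plus its sampling audit trail."""

    condition: str
    instances: list[KineticInstance]
    control: list[ControlCoefficientMatrix]
    jacobians: list[JacobianReport]
    attempts: int
    attempts_to_quota: int
    rejections: Counter
    surplus_accepted: int
    config: PipelineConfig
    dataset: ConditionDataset | None = None

    @property
    def n_accepted(self) -> int:
        return len(self.instances)

    @property
    def flux_ids(self) -> list[str]:
        return self.control[0].flux_ids

    @property
    def enzyme_ids(self) -> list[str]:
        return self.control[0].enzyme_ids

    def coefficient_samples(self, flux: str, enzyme: str) -> np.ndarray:
        """Per-instance C^{J_flux}_{E_enzyme} values (NaN dropped)."""
        i = self.flux_ids.index(flux)
        k = self.enzyme_ids.index(enzyme)
        vals = np.array([c.C[i, k] for c in self.control])
        return vals[~np.isnan(vals)]

    def median_matrix(self) -> pd.DataFrame:
        """Ensemble median control coefficient per enzyme-flux pair."""
        stack = np.array([c.C for c in self.control])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(stack, axis=0)
        return pd.DataFrame(med, index=self.flux_ids, columns=self.enzyme_ids)

    def summary(self) -> str:
        rej = ", ".join(f"{k}: {v}" for k, v in sorted(self.rejections.items())) or "none"
        med = self.median_matrix().abs()
        top = med.stack().sort_values(ascending=False).head(5)
        lines = [
            "Ensemble sampling results",
            "=" * 60,
            f"condition:          {self.condition}",
            f"retained instances: {self.n_accepted} (quota {self.config.n_target})",
            f"sampling attempts:  {self.attempts} "
            f"(quota reached after {self.attempts_to_quota})",
            f"rejections:         {rej}",
            f"surplus accepted:   {self.surplus_accepted}",
            "",
            "largest |median control coefficients| (flux <- enzyme):",
        ]
        for (flux, enz), val in top.items():
            sign_val = self.median_matrix().loc[flux, enz]
            lines.append(f"  {flux:>12s} <- {enz:<12s} {sign_val:+.3f}")
        return "\n".join(lines)

    def to_long_frame(self) -> pd.DataFrame:
        """Per-instance coefficients in long format (for TSV export)."""
        rows = []
        for n, c in enumerate(self.control):
            for i, flux in enumerate(c.flux_ids):
                for k, enz in enumerate(c.enzyme_ids):
                    rows.append((self.condition, n, flux, enz, c.C[i, k]))
        return pd.DataFrame(
            rows, columns=["condition", "instance", "flux", "enzyme", "coefficient"]
        )

    def manifest(self) -> dict:
        return {
            "condition": self.condition,
            "n_accepted": self.n_accepted,
            "attempts": self.attempts,
            "attempts_to_quota": self.attempts_to_quota,
            "surplus_accepted": self.surplus_accepted,
            "rejections": dict(self.rejections),
            "base_seed": self.config.base_seed,
            "n_target": self.config.n_target,
            "min_attempts": self.config.min_attempts,
            "stability_threshold": self.config.stability_threshold,
        }

    def plot_heatmap(self, fluxes=None, enzymes=None, ax=None):
        """Heat map of median control coefficients (blue positive, red negative)."""
        import matplotlib.pyplot as plt
        import seaborn as sns

        med = self.median_matrix()
        if fluxes is not None:
            med = med.loc[fluxes]
        if enzymes is not None:
            med = med[enzymes]
        if ax is None:
            _, ax = plt.subplots(figsize=(0.6 * med.shape[1] + 2, 0.4 * med.shape[0] + 2))
        sns.heatmap(med, center=0.0, cmap="RdBu", annot=med.shape[0] <= 12, fmt=".2f", ax=ax)
        ax.set_xlabel("enzyme")
        ax.set_ylabel("flux")
        ax.set_title(self.condition)
        return ax


class EnsembleModel:
    """Sampling campaign for one growth condition.

    Parameters
    ----------
    model : MetabolicModel
        Validated network with mechanisms and regulators.
    dataset : ConditionDataset
        Processed measurements: concentration bounds + balanced fluxes.
    std_gibbs : StandardGibbs
        Standard Gibbs energy range per non-drain reaction (kJ/mol).
    config : PipelineConfig, optional
    """

    def __init__(
        self,
        model: MetabolicModel,
        dataset: ConditionDataset,
        std_gibbs: StandardGibbs,
        config: PipelineConfig | None = None,
    ) -> None:
        self.model = model
        self.dataset = dataset
        self.std_gibbs = std_gibbs
        self.config = config or PipelineConfig()

    def fit(self, base_seed: int | None = None) -> EnsembleResult:
        """Sample until the quota of stable, feasible instances is retained."""
        cfg = self.config if base_seed is None else replace(self.config, base_seed=base_seed)
        label = self.dataset.label
        instances: list[KineticInstance] = []
        jacobians: list[JacobianReport] = []
        rejections: Counter = Counter()
        attempts = 0
        attempts_to_quota = 0
        surplus = 0
        while attempts < cfg.min_attempts or len(instances) < cfg.n_target:
            if attempts >= cfg.attempt_cap:
                raise RuntimeError(
                    f"condition {label!r}: quota not met after {attempts} attempts "
                    f"({len(instances)} accepted; rejections {dict(rejections)})"
                )
            rng = attempt_rng(cfg.base_seed, label, attempts)
            attempts += 1
            try:
                inst = sample_instance(
                    self.model, self.dataset, self.std_gibbs, rng,
                    cfg=cfg.thermo, seed=attempts - 1,
                )
            except (ThermoInfeasible, KineticSolveError) as exc:
                rejections[getattr(exc, "stage", "unknown")] += 1
                continue
            report = jacobian_at_reference(
                inst, threshold=cfg.stability_threshold, instance_id=attempts - 1
            )
            if cfg.filter_unstable and not report.stable:
                rejections["unstable"] += 1
                continue
            if len(instances) < cfg.n_target:
                instances.append(inst)
                jacobians.append(report)
                if len(instances) == cfg.n_target:
                    attempts_to_quota = attempts
            else:
                surplus += 1
            if (
                attempts >= cfg.min_attempts
                and len(instances) < cfg.n_target
                and len(instances) / attempts < cfg.acceptance_floor
                and attempts >= min(cfg.attempt_cap, 10 * cfg.min_attempts)
            ):
                raise RuntimeError(
                    f"condition {label!r}: acceptance rate "
                    f"{len(instances) / attempts:.4f} below floor after {attempts} attempts"
                )
        control = [
            flux_control_coefficients(inst, instance_id=i)
            for i, inst in enumerate(instances)
        ]
        return EnsembleResult(
            condition=label,
            instances=instances,
            control=control,
            jacobians=jacobians,
            attempts=attempts,
            attempts_to_quota=attempts_to_quota or attempts,
            rejections=rejections,
            surplus_accepted=surplus,
            config=cfg,
            dataset=self.dataset,
        )


def run_condition(
    model: MetabolicModel,
    dataset: ConditionDataset,
    std_gibbs: StandardGibbs,
    config: PipelineConfig | None = None,
) -> EnsembleResult:
    """Functional entry point equivalent to ``EnsembleModel(...).fit()``."""
    return EnsembleModel(model, dataset, std_gibbs, config).fit()


# ---------------------------------------------------------------------
# cross-condition diagnostics


def median_control_table(ensembles: list[EnsembleResult]) -> pd.DataFrame:
    """Long-format median table: one row per (flux, enzyme), one column per
    condition — the table heat maps are drawn from.

    Pairs undefined in every instance of a condition (zero-flux rows)
    propagate as NaN.
    """
    if not ensembles:
        raise ValueError("no ensembles given")
    frames = {}
    for res in ensembles:
        med = res.median_matrix().stack(future_stack=True)
        frames[res.condition] = med
    table = pd.DataFrame(frames)
    table.index.names = ["flux", "enzyme"]
    return table.reset_index()


def ks_compare(
    ensemble_a: EnsembleResult,
    ensemble_b: EnsembleResult,
    pair: tuple[str, str],
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test on one enzyme-flux pair.

    Returns (D statistic, p-value) comparing the per-instance coefficient
    distributions of the two ensembles.
    """
    import scipy.stats

    flux, enzyme = pair
    a = ensemble_a.coefficient_samples(flux, enzyme)
    b = ensemble_b.coefficient_samples(flux, enzyme)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"pair ({flux}, {enzyme}): need >= 2 defined values per side "
            f"(got {len(a)} and {len(b)})"
        )
    stat = scipy.stats.ks_2samp(a, b, alternative="two-sided")
    return float(stat.statistic), float(stat.pvalue)


def ks_table(
    ensemble_a: EnsembleResult, ensemble_b: EnsembleResult
) -> pd.DataFrame:
    """K-S comparison over all defined pairs, with Benjamini-Hochberg
    adjusted p-values alongside the raw ones."""
    rows = []
    for flux in ensemble_a.flux_ids:
        for enzyme in ensemble_a.enzyme_ids:
            try:
                d, p = ks_compare(ensemble_a, ensemble_b, (flux, enzyme))
            except ValueError:
                continue
            rows.append((flux, enzyme, d, p))
    df = pd.DataFrame(rows, columns=["flux", "enzyme", "D", "p"])
    if len(df):
        from statsmodels.stats.multitest import multipletests

        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def convergence_curve(
    ensemble: EnsembleResult, pair: tuple[str, str], checkpoints: list[int]
) -> list[float]:
    """Running medians of one pair over the first n retained instances.

    Instance order is acceptance order; each checkpoint n must not exceed
    the ensemble size.
    """
    flux, enzyme = pair
    i = ensemble.flux_ids.index(flux)
    k = ensemble.enzyme_ids.index(enzyme)
    vals = np.array([c.C[i, k] for c in ensemble.control])
    out = []
    for n in checkpoints:
        if n > len(vals):
            raise ValueError(f"checkpoint {n} exceeds ensemble size {len(vals)}")
        head = vals[:n]
        head = head[~np.isnan(head)]
        out.append(float(np.median(head)) if len(head) else float("nan"))
    return out


def save_run(
    out_dir: str | Path, ensembles: list[EnsembleResult], model: MetabolicModel
) -> None:
    """Write medians, per-instance coefficients and run metadata as TSV/JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    median_control_table(ensembles).to_csv(out / "median_control.tsv", sep="\t", index=False)
    pd.concat([r.to_long_frame() for r in ensembles]).to_csv(
        out / "control_coefficients.tsv", sep="\t", index=False
    )
    manifest = {
        "model": model.summary(),
        "conditions": [r.manifest() for r in ensembles],
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
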