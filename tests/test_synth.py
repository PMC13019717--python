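"""Synthetic data generator: templates, ground truth, condition series."""

import numpy as np
import pytest

import kincontrol as kc
from kincontrol.model import remove_regulation
from kincontrol.synth import (
    SyntheticSpec,
    generate_condition_series,
    generate_ground_truth,
    generate_toy_model,
    standard_gibbs_table,
)


class TestTemplates:
    def test_linear_chain_counts(self):
        m = generate_toy_model(SyntheticSpec(template="linear_chain", chain_length=3))
        assert len(m.reactions) == 5  # uptake + 3 conversions + secretion
        assert len(m.metabolites) == 4

    def test_branched_has_one_allosteric_and_one_competitive(self, branched_model):
        assert sum(r.is_allosteric for r in branched_model.reactions.values()) == 1
        comp = [
            g
            for r in branched_model.reactions.values()
            for g in r.regulations
            if g.kind == "competitive_inhibitor"
        ]
        assert len(comp) == 1
        assert any(r.is_drain for r in branched_model.reactions.values())

    def test_two_compartment_distinct_pH(self):
        m = generate_toy_model(SyntheticSpec(template="two_compartment_mini"))
        comps = {c.id: c.pH for c in m.compartments.values()}
        assert len(comps) == 2
        assert len(set(comps.values())) == 2
        met_comps = {met.compartment for met in m.metabolites.values()}
        assert met_comps == set(comps)

    def test_unknown_template_rejected(self):
        with pytest.raises(ValueError, match="template"):
            generate_toy_model(SyntheticSpec(template="nonsense"))


class TestGroundTruth:
    def test_generating_instance_self_consistent(self, branched_truth):
        assert branched_truth.instance.max_steady_state_error() <= 1e-9
        for cond in branched_truth.conditions:
            v = branched_truth.instance.evaluate(cond.u_star, cond.enzyme_levels)
            scale = np.max(np.abs(cond.v_star))
            assert np.max(np.abs(v - cond.v_star)) <= 1e-9 * scale

    def test_true_control_rows_sum_to_one(self, branched_truth):
        for cond in branched_truth.conditions:
            np.testing.assert_allclose(cond.control.row_sums(), 1.0, atol=1e-6)

    def test_uptake_flux_monotone_in_dilution_rate(self, branched_truth):
        """More uptake drive -> non-decreasing uptake flux, verified by the
        direct steady-state simulation behind each condition."""
        sweep = [c for c in branched_truth.conditions if "glucose" in c.label]
        sweep.sort(key=lambda c: c.dilution_rate)
        uptakes = [c.v_star[0] for c in sweep]
        assert np.all(np.diff(uptakes) >= -1e-12)

    def test_nine_conditions_by_default(self, branched_truth):
        assert len(branched_truth.conditions) == 9
        labels = [c.label for c in branched_truth.conditions]
        assert sum("glucose" in l for l in labels) == 5
        for lim in ("phosphate", "ammonia", "leucine", "uracil"):
            assert sum(lim in l for l in labels) == 1


class TestConditionSeries:
    def test_noiseless_measurements_equal_truth(self, branched_model, branched_truth):
        spec0 = SyntheticSpec(seed=0, noise_sigma=0.0)
        datasets = generate_condition_series(branched_truth, spec0)
        met_ids = branched_model.metabolite_ids
        for ds, cond in zip(datasets, branched_truth.conditions):
            for i, m in enumerate(met_ids):
                if branched_model.metabolites[m].is_fixed:
                    continue
                assert ds.bounds.reference[m] == pytest.approx(cond.x_star[i])
                assert ds.bounds.lower[m] <= cond.x_star[i] <= ds.bounds.upper[m]

    def test_noisy_bounds_usually_bracket_truth(self, branched_model, branched_truth):
        """At sigma = 0.2 the [0.5c, 1.5c] box contains the true value when
        the multiplicative error is within [2/3, 2], i.e. with probability
        ~95.7% per metabolite (lognormal CDF); across seeds the coverage
        stays near that rate."""
        met_ids = branched_model.metabolite_ids
        inside = total = 0
        for seed in range(30):
            spec = SyntheticSpec(seed=0, noise_sigma=0.2)
            rng = np.random.default_rng(seed)
            datasets = generate_condition_series(branched_truth, spec, rng=rng)
            for ds, cond in zip(datasets, branched_truth.conditions):
                for i, m in enumerate(met_ids):
                    if branched_model.metabolites[m].is_fixed:
                        continue
                    total += 1
                    if ds.bounds.lower[m] <= cond.x_star[i] <= ds.bounds.upper[m]:
                        inside += 1
        from scipy.stats import norm

        expected = norm.cdf(np.log(2.0) / 0.2) - norm.cdf(np.log(2.0 / 3.0) / 0.2)
        assert inside / total == pytest.approx(expected, abs=0.02)

    def test_no_measurements_gives_default_boxes(self, branched_truth):
        spec = SyntheticSpec(seed=0, measured="none")
        datasets = generate_condition_series(branched_truth, spec)
        ds = datasets[0]
        for m, lo in ds.bounds.lower.items():
            assert lo == pytest.approx(1e-15)
            assert ds.bounds.upper[m] == pytest.approx(10.0)

    def test_no_warnings_at_zero_noise(self, branched_truth, recwarn):
        spec = SyntheticSpec(seed=0, noise_sigma=0.0)
        generate_condition_series(branched_truth, spec)
        assert not [w for w in recwarn if issubclass(w.category, UserWarning)]


class TestControlRecovery:
    def test_median_signs_recover_ground_truth(
        self, branched_model, branched_truth, branched_std
    ):
        """Headline recovery surface: on noiseless data, the ensemble median
        control coefficients match the ground-truth signs for >= 90% of
        pairs with |true C| > 0.1."""
        spec0 = SyntheticSpec(seed=0, noise_sigma=0.0)
        datasets = generate_condition_series(branched_truth, spec0)
        cond_idx = 2
        cfg = kc.PipelineConfig(n_target=100, min_attempts=120, base_seed=0)
        res = kc.EnsembleModel(
            branched_model, datasets[cond_idx], branched_std, cfg
        ).fit()
        med = res.median_matrix().to_numpy()
        true_C = branched_truth.conditions[cond_idx].control.C
        mask = np.isfinite(true_C) & (np.abs(true_C) > 0.1) & np.isfinite(med)
        agree = np.sign(med[mask]) == np.sign(true_C[mask])
        assert mask.sum() >= 10
        assert agree.mean() >= 0.90

    def test_regulation_removal_weakens_supplier_control(
        self, branched_model, branched_datasets, branched_std
    ):
        """Removing the allosteric ATP inhibition of the fermentative step
        weakens the negative median control of the ATP supplier (the
        respiratory branch) over the fermentative flux — the toy-scale
        analogue of removing a phosphate inhibition and watching its
        negative control over the downstream branch soften."""
        cfg = kc.PipelineConfig(n_target=30, min_attempts=30, base_seed=11)
        base = kc.EnsembleModel(
            branched_model, branched_datasets[2], branched_std, cfg
        ).fit()
        removed_model = remove_regulation(branched_model, "FERM", "atp_c")
        removed = kc.EnsembleModel(
            removed_model, branched_datasets[2], branched_std, cfg
        ).fit()
        c_base = base.median_matrix().loc["FER_sec", "RESP"]
        c_removed = removed.median_matrix().loc["FER_sec", "RESP"]
        assert c_base < 0
        assert abs(c_removed) < abs(c_base)


class TestAtpCompetitionFlip:
    def test_kinase_control_flips_sign_with_supply(self):
        """On the purpose-built ATP-competition template, the ground-truth
        control of the hexokinase-like enzyme over the competing storage
        flux is negative at the lowest uptake drive and positive at the
        highest — the qualitative supply-dependent sign flip."""
        spec = SyntheticSpec(seed=0, template="atp_competition_mini")
        model = generate_toy_model(spec)
        truth = generate_ground_truth(model, spec)
        rids = model.reaction_ids
        i, k = rids.index("TRE"), rids.index("HEX")
        sweep = sorted(
            (c for c in truth.conditions if "glucose" in c.label),
            key=lambda c: c.dilution_rate,
        )
        c_low = sweep[0].control.C[i, k]
        c_high = sweep[-1].control.C[i, k]
        assert c_low < -0.02
        assert c_high > 0.02
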