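"""Global-fit checks: grid enumeration, recovery, invariances, refusals."""

import numpy as np
import pytest
from dataclasses import replace

from accelstab.dataset import StabilityDataset
from accelstab.fitting import (
    FitError,
    FitOptions,
    enumerate_model_grid,
    fit_all,
    fit_model,
)
from accelstab.kinetics import (
    T_REF,
    KineticModelSpec,
    KineticParameters,
    TemperatureProfile,
)
from accelstab.simulate import generate_stability_dataset


class TestGridEnumeration:
    def test_counts(self):
        assert len(enumerate_model_grid(1, [0, 1], [0])) == 2
        assert len(enumerate_model_grid(1, [0, 1, 2], [0, 1])) == 6
        # one-step: 1 n * 2 m; two-step: 1 n1 * (1 n2 * 2 m2)
        assert len(enumerate_model_grid(2, [1], [0, 1])) == 4

    def test_two_step_first_step_never_autocatalytic(self):
        for spec in enumerate_model_grid(2, [0, 1], [0, 0.5, 1]):
            if spec.n_steps == 2:
                assert spec.orders[0][1] == 0.0

    def test_order_is_deterministic_one_step_first(self):
        grid = enumerate_model_grid(2, [1, 0], [1, 0])
        steps = [s.n_steps for s in grid]
        assert steps == sorted(steps)
        one_step = [s.orders[0] for s in grid if s.n_steps == 1]
        assert one_step == sorted(one_step)


class TestFitModel:
    def test_noise_free_recovery_of_activation_energy(self, first_order_cfg):
        truth = first_order_cfg.assays["purity_pct"]
        quiet = replace(first_order_cfg, assays={"purity_pct": replace(truth, noise_sd=0.0)})
        data = generate_stability_dataset(quiet, 1).select("purity_pct")
        fit = fit_model(data, truth.spec)
        assert fit.params.Ea[0] == pytest.approx(truth.params.Ea[0], rel=1e-3)
        assert fit.rmse < 1e-6

    def test_constant_data_gives_flat_model(self, rng):
        values = 50.0 + rng.normal(0, 0.5, size=32)
        records = [
            {"assay": "a", "temp_C": tc, "time_months": t, "replicate": 1, "value": v}
            for v, (tc, t) in zip(
                values,
                [(tc, t) for tc in (5, 25, 40, 45) for t in np.linspace(0, 3, 8)],
            )
        ]
        data = StabilityDataset.from_records(records)
        fit = fit_model(data, KineticModelSpec(((0.0, 0.0),)))
        # flat data: predicted drift stays within the noise and rmse ~ data SD
        pred = fit.predict(TemperatureProfile.isothermal(45.0, duration_months=3.0), [0.0, 3.0])
        assert abs(pred[1] - pred[0]) < 1.0
        assert fit.rmse == pytest.approx(np.std(values), rel=0.25)

    def test_nested_model_rss_ordering(self):
        """A Prout-Tompkins fit can only improve on its nested m=0 reduction."""
        from accelstab.simulate import aggregation_scenario

        data = generate_stability_dataset(aggregation_scenario(), 7).select("radius_nm")
        rss_pt = fit_model(data, KineticModelSpec(((1.0, 1.0),))).rss
        rss_fo = fit_model(data, KineticModelSpec(((1.0, 0.0),))).rss
        assert rss_pt <= rss_fo * (1 + 1e-9)

    def test_reparameterization_round_trip(self, first_order_fit):
        """A = k_ref*exp(Ea/(R*T_ref)) reproduces identical predictions."""
        from accelstab.kinetics import GAS_CONSTANT

        p = first_order_fit.params
        k_ref = p.k(0, T_REF)
        rebuilt = KineticParameters(
            A=(k_ref * np.exp(p.Ea[0] / (GAS_CONSTANT * T_REF)),),
            Ea=p.Ea,
            y0=p.y0,
            dY=p.dY,
            alpha0=p.alpha0,
        )
        profile = TemperatureProfile.isothermal(5.0, duration_months=36.0)
        t = np.linspace(0, 36, 19)
        a = first_order_fit.predict(profile, t)
        from accelstab.kinetics import predict_signal

        b = predict_signal(first_order_fit.spec, rebuilt, profile, t)
        assert np.allclose(a, b, rtol=1e-6)

    def test_scale_equivariance(self, first_order_cfg, first_order_data, first_order_fit):
        truth = first_order_cfg.assays["purity_pct"]
        scaled = first_order_data.with_values(first_order_data.frame["value"].to_numpy() * 10.0)
        fit10 = fit_model(scaled, truth.spec)
        assert fit10.params.y0 == pytest.approx(10 * first_order_fit.params.y0, rel=1e-3)
        assert fit10.params.dY[0] == pytest.approx(10 * first_order_fit.params.dY[0], rel=1e-3)
        assert fit10.rmse == pytest.approx(10 * first_order_fit.rmse, rel=1e-3)
        assert fit10.params.Ea[0] == pytest.approx(first_order_fit.params.Ea[0], rel=1e-3)

    def test_rmse_convention_and_residuals(self, first_order_fit):
        f = first_order_fit
        assert f.rmse == pytest.approx(np.sqrt(f.rss / f.n_points), rel=1e-12)
        assert np.dot(f.residuals, f.residuals) == pytest.approx(f.rss, rel=1e-12)
        assert f.n_params < f.n_points

    def test_overparameterized_refusal(self):
        records = [
            {"assay": "a", "temp_C": tc, "time_months": t, "replicate": 1, "value": 1.0 + t}
            for tc in (5, 45)
            for t in (0.0, 1.0, 2.0)
        ]
        data = StabilityDataset.from_records(records)
        with pytest.raises(FitError):
            fit_model(data, KineticModelSpec(((1.0, 0.0), (1.0, 1.0))))


class TestFitAll:
    def test_grid_of_one(self, first_order_data):
        fits = fit_all(first_order_data, [KineticModelSpec(((1.0, 0.0),))])
        assert len(fits) == 1

    def test_unfittable_spec_skipped(self, first_order_cfg):
        # 2 temperatures x 3 times x 1 replicate = 6 points: the two-step
        # model (7 free parameters) is refused, the one-step models fit
        tiny = replace(
            first_order_cfg,
            times=(0.0, 1.0, 3.0),
            replicates=1,
            temperatures_c=(5.0, 45.0),
        )
        data = generate_stability_dataset(tiny, 3).select("purity_pct")
        grid = [
            KineticModelSpec(((1.0, 0.0),)),
            KineticModelSpec(((1.0, 0.0), (1.0, 1.0))),
            KineticModelSpec(((2.0, 0.0),)),
        ]
        fits = fit_all(data, grid)
        assert 0 < len(fits) < len(grid)
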