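import math

import numpy as np
import pytest

from cck3r.pharm import (
    CellFluorescenceRecord,
    DoseResponseDataset,
    binding_ratio,
    dataset_from_frame,
    delta_ct_expression,
    fit_dose_response,
    four_pl,
    knockdown_fraction,
    rfu_ratio,
)
from cck3r.synth import PlateSpec, make_dose_response


class TestFourPL:
    def test_midpoint_identity(self):
        ec50 = 3.162
        y = four_pl(ec50, bottom=1.0, top=3.0, log_ec50=math.log10(ec50), hill=1.3)
        assert y == pytest.approx(2.0)

    def test_asymptotes(self):
        kw = dict(bottom=1.0, top=3.0, log_ec50=0.5, hill=1.0)
        assert four_pl(1e-9, **kw) == pytest.approx(1.0, abs=1e-6)
        assert four_pl(1e12, **kw) == pytest.approx(3.0, abs=1e-6)

    def test_monotone_increasing_for_positive_hill(self):
        y1, y10 = four_pl([1.0, 10.0], 1.0, 3.0, math.log10(3.162), 1.0)
        assert y1 < y10

    def test_rejects_nonpositive_dose(self):
        with pytest.raises(ValueError):
            four_pl(0.0, 1, 3, 0.5, 1)


class TestDataset:
    def test_requires_four_doses(self):
        with pytest.raises(ValueError):
            DoseResponseDataset(doses=(1, 2, 3), responses=((1,), (2,), (3,)))

    def test_requires_increasing_doses(self):
        with pytest.raises(ValueError):
            DoseResponseDataset(doses=(1, 3, 2, 4), responses=((1,),) * 4)

    def test_from_frame_roundtrip(self):
        import pandas as pd

        frame = pd.DataFrame(
            {"dose_nM": [1, 1, 10, 10, 100, 100, 1000, 1000], "response": range(8)}
        )
        data = dataset_from_frame(frame)
        assert data.doses == (1.0, 10.0, 100.0, 1000.0)
        assert data.responses[0] == (0.0, 1.0)


class TestFitDoseResponse:
    @pytest.mark.parametrize(
        "ec50,hill,bottom,top",
        [(3.23, 1.0, 1.0, 3.0), (0.5, 1.7, 0.2, 5.0), (40.0, 0.7, 1.0, 2.0)],
    )
    def test_noiseless_recovery(self, ec50, hill, bottom, top):
        spec = PlateSpec(ec50_nM=ec50, hill=hill, bottom=bottom, top=top, noise=0.0)
        fit = fit_dose_response(make_dose_response(spec))
        assert fit.converged
        assert fit.ec50_or_ic50 == pytest.approx(ec50, rel=1e-6)
        assert fit.hill == pytest.approx(hill, rel=1e-4)
        assert fit.top >= fit.bottom

    def test_antagonist_noiseless_recovery(self):
        spec = PlateSpec(ec50_nM=12.3, mode="antagonist", noise=0.0)
        fit = fit_dose_response(make_dose_response(spec))
        assert fit.converged
        assert fit.ec50_or_ic50 == pytest.approx(12.3, rel=1e-6)
        assert fit.hill < 0

    def test_consistency_more_replicates_reduce_error(self):
        """Median |relative error| of EC50 shrinks as replicates grow 3 -> 12."""
        errors = {}
        for reps in (3, 12):
            errs = []
            for seed in range(60):
                spec = PlateSpec(ec50_nM=3.23, replicates=reps, noise=0.10, seed=seed)
                fit = fit_dose_response(make_dose_response(spec))
                errs.append(abs(fit.ec50_or_ic50 - 3.23) / 3.23)
            errors[reps] = float(np.median(errs))
        assert errors[12] < errors[3]

    def test_direction_mismatch_flagged(self):
        increasing = make_dose_response(PlateSpec(ec50_nM=3.0, noise=0.0))
        decreasing = make_dose_response(
            PlateSpec(ec50_nM=3.0, mode="antagonist", noise=0.0)
        )
        as_antagonist = DoseResponseDataset(
            doses=increasing.doses, responses=increasing.responses, mode="antagonist"
        )
        as_agonist = DoseResponseDataset(
            doses=decreasing.doses, responses=decreasing.responses, mode="agonist"
        )
        assert fit_dose_response(as_antagonist).direction_mismatch
        assert fit_dose_response(as_agonist).direction_mismatch
        assert not fit_dose_response(increasing).direction_mismatch

    def test_hill_fixed_option(self):
        spec = PlateSpec(ec50_nM=3.23, hill=1.0, noise=0.0)
        fit = fit_dose_response(make_dose_response(spec), hill_fixed=True)
        assert fit.hill == pytest.approx(1.0, abs=1e-6)
        assert fit.ec50_or_ic50 == pytest.approx(3.23, rel=1e-6)


class TestRatios:
    def test_rfu_identity_and_doubling(self):
        assert rfu_ratio([2.0, 2.0], [2.0, 2.0]) == pytest.approx(1.0)
        assert rfu_ratio([1.0, 3.0], [2.0, 6.0]) == pytest.approx(2.0)

    def test_rfu_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            rfu_ratio([0.0, 0.0], [1.0])

    def test_rfu_scale_invariance(self):
        before, after = [1.0, 2.0], [3.0, 5.0]
        base = rfu_ratio(before, after)
        scaled = rfu_ratio([7.0 * b for b in before], [7.0 * a for a in after])
        assert scaled == pytest.approx(base)

    def test_binding_ratio_equal_signals(self):
        cells = [CellFluorescenceRecord(str(i), 2.0, 2.0) for i in range(4)]
        summary = binding_ratio(cells)
        assert summary.mean == pytest.approx(1.0)
        assert summary.sem == pytest.approx(0.0)

    def test_binding_ratio_example(self):
        cells = [
            CellFluorescenceRecord("a", 2, 4),
            CellFluorescenceRecord("b", 3, 6),
            CellFluorescenceRecord("c", 1, 2),
        ]
        summary = binding_ratio(cells)
        assert summary.mean == pytest.approx(0.5)
        assert summary.sem == pytest.approx(0.0)
        assert summary.n == 3

    def test_competitive_block_halves_mean(self):
        control = [CellFluorescenceRecord(str(i), 4.0, 2.0) for i in range(5)]
        blocked = [CellFluorescenceRecord(str(i), 2.0, 2.0) for i in range(5)]
        assert binding_ratio(blocked).mean == pytest.approx(
            binding_ratio(control).mean / 2
        )

    def test_binding_ratio_scale_invariance(self):
        cells = [CellFluorescenceRecord("a", 3.0, 2.0), CellFluorescenceRecord("b", 1.0, 4.0)]
        scaled = [
            CellFluorescenceRecord(c.cell_id, 5 * c.f_anti_ha, 5 * c.f_anti_flag)
            for c in cells
        ]
        assert binding_ratio(scaled).mean == pytest.approx(binding_ratio(cells).mean)

    def test_zero_flag_rejected(self):
        with pytest.raises(ValueError):
            binding_ratio([CellFluorescenceRecord("a", 1.0, 0.0)])


class TestDeltaCt:
    def test_identities(self):
        assert delta_ct_expression(20.0, 20.0) == pytest.approx(1.0)
        assert delta_ct_expression(21.0, 20.0) == pytest.approx(0.5)

    def test_knockdown_fraction(self):
        assert knockdown_fraction(0.4, 1.0) == pytest.approx(0.6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            delta_ct_expression(float("nan"), 20.0)
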