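"""Network wiring, unit dynamics and the drive-multiplier interface."""

import numpy as np
import pytest

from legsearch import build_network, default_config, motoneuron_drive, step_units
from legsearch.config import ExtraSynapseConfig
from legsearch.errors import ConfigurationError
from legsearch.network import (CPG_LABELS, IN_LABELS, MN_LABELS, UNIT_LABELS,
                               audit_wiring)

# The reference adjacency of the two local networks, sign for sign.
E, I = "excitatory", "inhibitory"
REFERENCE_WIRING = [
    ("C3", "C4", I), ("C4", "C3", I), ("C5", "C6", I), ("C6", "C5", I),
    ("C4", "IN7", E), ("C4", "IN8", E), ("C3", "IN9", E), ("C3", "IN10", E),
    ("IN7", "MN(LF)", I), ("IN8", "MN(LS)", I),
    ("IN9", "MN(DF)", I), ("IN10", "MN(DS)", I),
    ("C5", "IN13", E), ("C5", "IN14", E), ("C6", "IN15", E), ("C6", "IN16", E),
    ("IN13", "MN(EF)", I), ("IN14", "MN(ES)", I),
    ("IN15", "MN(FF)", I), ("IN16", "MN(FS)", I),
    ("IN11", "C3", I), ("IN11", "C4", I),
    ("IN12", "C3", E), ("IN12", "C4", E),
    ("IN17", "C5", I), ("IN17", "C6", I),
    ("IN18", "C6", E),
]


class TestBuildNetwork:
    def test_unit_census(self, config):
        model = build_network(config)
        assert len(model.units) == 24
        assert len(CPG_LABELS) == 4 and len(IN_LABELS) == 12 and len(MN_LABELS) == 8
        assert set(model.units) == set(UNIT_LABELS)

    def test_wiring_audit_sign_for_sign(self, config):
        model = build_network(config)
        assert audit_wiring(model, REFERENCE_WIRING) == []

    def test_zero_drive_config_builds(self, config):
        d = config.network.drives
        for name in type(d).model_fields:
            setattr(d, name, 0.0)
        model = build_network(config)
        assert len(model.synapses) == 27

    def test_unknown_unit_label_rejected(self, config):
        config.network.extra_synapses = [ExtraSynapseConfig(
            source="C9", target="C3", sign="excitatory", conductance=1.0)]
        with pytest.raises(ConfigurationError):
            build_network(config)

    def test_sensory_relays_target_the_right_cells(self, config):
        model = build_network(config)
        targets = {(s.source, s.target) for s in model.synapses}
        assert ("IN12", "C3") in targets and ("IN12", "C4") in targets
        assert ("IN18", "C6") in targets


class TestStepUnits:
    def test_outputs_stay_in_unit_interval(self, config):
        model = build_network(config)
        model = step_units(model, {"g_beta": 1.0, "g_gamma": 1.0},
                           dt=0.1, n_steps=5000)
        for unit in model.units.values():
            assert 0.0 <= unit.output <= 1.0
            assert np.all(np.isfinite(unit.state))

    def test_zero_drive_rests_at_fixed_point(self, config):
        d = config.network.drives
        for name in type(d).model_fields:
            setattr(d, name, 0.0)
        config.network.c3_init_offset_mv = 0.0
        model = build_network(config)
        # settle (the slow inactivation variable takes seconds), then check
        # the state stops moving
        model = step_units(model, {"g_beta": 0.0, "g_gamma": 0.0}, 1.0, 12_000)
        y1 = model.state_vector()
        model = step_units(model, {"g_beta": 0.0, "g_gamma": 0.0}, 1.0, 2000)
        y2 = model.state_vector()
        assert np.allclose(y1, y2, atol=1e-4)
        # and all outputs are near zero (quiescent network)
        assert all(u.output < 0.05 for u in model.units.values())

    def test_half_center_antiphase(self, config):
        # with the gamma gate high the levator-depressor half-center
        # alternates; C3 and C4 outputs must be anticorrelated
        model = build_network(config)
        out3, out4 = [], []
        for _ in range(300):
            model = step_units(model, {"g_beta": 1.0, "g_gamma": 1.0}, 0.5, 40)
            out3.append(model.units["C3"].output)
            out4.append(model.units["C4"].output)
        out3, out4 = np.array(out3[100:]), np.array(out4[100:])
        assert out3.std() > 0.1 and out4.std() > 0.1   # both oscillate
        r = np.corrcoef(out3, out4)[0, 1]
        assert r < -0.5
        assert np.all(out3 * out4 < 0.5)               # never both fully on

    def test_saturating_central_inhibition_silences_in7(self, config):
        config.network.drives.g_d7 = 10.0
        model = build_network(config)
        model = step_units(model, {"g_beta": 1.0, "g_gamma": 1.0}, 0.5, 8000)
        assert model.units["IN7"].output < 1e-3

    def test_determinism_bit_identical(self, config):
        runs = []
        for _ in range(2):
            model = build_network(default_config())
            model = step_units(model, {"g_beta": 1.0, "g_gamma": 1.0}, 0.1, 2000)
            runs.append(model.state_vector())
        assert np.array_equal(runs[0], runs[1])

    def test_bad_dt_rejected(self, config):
        model = build_network(config)
        with pytest.raises(ConfigurationError):
            step_units(model, {}, dt=2.0)


class TestMotoneuronDrive:
    def test_identity_multipliers_change_nothing(self, config):
        model = build_network(config)
        base = motoneuron_drive(model, {})
        same = motoneuron_drive(model, {k: 1.0 for k in (
            "fast_levator", "slow_levator", "fast_depressor", "slow_depressor",
            "fast_extensor", "slow_extensor", "fast_flexor", "slow_flexor")})
        assert base == same

    def test_zero_multipliers_silence_all_mns(self, config):
        model = build_network(config)
        zeros = {f"{s}_{r}": 0.0 for s in ("fast", "slow")
                 for r in ("levator", "depressor", "extensor", "flexor")}
        inputs = motoneuron_drive(model, zeros)
        assert all(v == 0.0 for v in inputs.values())
        model = step_units(model, {"g_beta": 1.0, "g_gamma": 1.0}, 0.5, 4000)
        for lbl in MN_LABELS:
            assert model.units[lbl].output < 1e-3

    def test_stepping_fast_extensor_multiplier_reactivates(self, config):
        model = build_network(config)
        motoneuron_drive(model, {"fast_extensor": 0.0})
        model = step_units(model, {"g_beta": 1.0, "g_gamma": 1.0}, 0.5, 4000)
        assert model.units["MN(EF)"].output < 1e-3
        motoneuron_drive(model, {"fast_extensor": 1.0})
        model = step_units(model, {"g_beta": 1.0, "g_gamma": 1.0}, 0.5, 400)
        assert model.units["MN(EF)"].output > 0.5

    @pytest.mark.parametrize("bad", [{"fast_extensor": 1.5},
                                     {"fast_retractor": 1.0}])
    def test_invalid_overrides_rejected(self, config, bad):
        model = build_network(config)
        with pytest.raises(ConfigurationError):
            motoneuron_drive(model, bad)
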