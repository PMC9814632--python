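"""ADI+Heun solver: fixed points, conservation, scheme accuracy, and
the forcing-protocol runner."""

import numpy as np
import pytest

from turingforce.config import ProtocolStage, SimulationConfig
from turingforce.model import ForcingParams, ModelParams, steady_state
from turingforce import pde


def _cfg(a=24.0, nx=32, ny=32, dx=0.25, dt=1e-3, noise_sd=0.0, seed=0,
         stages=None, **kw):
    return SimulationConfig(
        params=ModelParams(a=a),
        stages=tuple(stages or [ProtocolStage(duration=1.0)]),
        nx=nx, ny=ny, dx=dx, dt=dt, noise_sd=noise_sd, seed=seed, **kw,
    )


class TestInitialize:
    def test_zero_noise_gives_exactly_zero_fields(self):
        st = pde.initialize(_cfg(noise_sd=0.0))
        assert not st.u.any() and not st.v.any()

    def test_noise_statistics(self):
        st = pde.initialize(_cfg(nx=400, ny=400, noise_sd=0.01, seed=7))
        assert abs(st.u.mean()) < 3 * 0.01 / 400
        assert st.u.std() == pytest.approx(0.01, rel=0.02)

    def test_seed_determinism(self):
        a = pde.initialize(_cfg(noise_sd=0.01, seed=11))
        b = pde.initialize(_cfg(noise_sd=0.01, seed=11))
        c = pde.initialize(_cfg(noise_sd=0.01, seed=12))
        assert np.array_equal(a.u, b.u) and np.array_equal(a.v, b.v)
        assert not np.array_equal(a.u, c.u)


class TestStep:
    def test_homogeneous_steady_state_is_fixed_point(self):
        cfg = _cfg(a=24.0)
        u0, v0 = steady_state(cfg.params)
        st = pde.FieldState(u=np.full((32, 32), u0),
                            v=np.full((32, 32), v0), t=0.0)
        for i in range(1000):
            st = pde.step(st, cfg, cfg.stages[0], parity=i % 2)
        assert np.max(np.abs(st.u - u0)) < 1e-10
        assert np.max(np.abs(st.v - v0)) < 1e-10

    def test_diffusion_conserves_field_sums(self, rng):
        cfg = _cfg()
        st = pde.FieldState(u=rng.random((32, 32)), v=rng.random((32, 32)),
                            t=0.0)
        su, sv = st.u.sum(), st.v.sum()
        for i in range(200):
            st = pde.step(st, cfg, cfg.stages[0], parity=i % 2, react=False)
        assert abs(st.u.sum() - su) / su < 1e-9
        assert abs(st.v.sum() - sv) / sv < 1e-9

    def test_single_mode_decay_matches_scheme_symbol(self):
        # kinetics off: one Fourier mode must decay by the ADI
        # amplification factor of the discrete operator
        cfg = _cfg(nx=64, ny=64, dx=0.25, dt=2e-3)
        mx, my = 3, 5
        x = np.arange(64)
        X, Y = np.meshgrid(x, x)
        mode = np.cos(2 * np.pi * mx * X / 64) * np.cos(2 * np.pi * my * Y / 64)
        st = pde.FieldState(u=mode.copy(), v=mode.copy(), t=0.0)
        nsteps = 10
        for i in range(nsteps):
            st = pde.step(st, cfg, cfg.stages[0], parity=i % 2, react=False)
        bx = 2.0 - 2.0 * np.cos(2 * np.pi * mx / 64)
        by = 2.0 - 2.0 * np.cos(2 * np.pi * my / 64)

        def symbol(r):
            return ((1 - r * bx) * (1 - r * by)) / ((1 + r * bx) * (1 + r * by))

        r_u = cfg.dt / (2 * cfg.dx**2)
        r_v = cfg.params.sigma * cfg.params.c * cfg.dt / (2 * cfg.dx**2)
        amp_u = st.u.ravel() @ mode.ravel() / (mode.ravel() @ mode.ravel())
        amp_v = st.v.ravel() @ mode.ravel() / (mode.ravel() @ mode.ravel())
        assert amp_u == pytest.approx(symbol(r_u) ** nsteps, rel=0.01)
        assert amp_v == pytest.approx(symbol(r_v) ** nsteps, rel=0.01)

    def test_blow_up_reports_time(self):
        cfg = _cfg(dt=1e-3)
        bad = np.full((32, 32), 1e200)
        st = pde.FieldState(u=bad.copy(), v=bad.copy(), t=5.0)
        with pytest.raises(pde.BlowUpError) as exc:
            for i in range(50):
                st = pde.step(st, cfg, cfg.stages[0], parity=i % 2)
        assert exc.value.t > 5.0


class TestAccuracy:
    def test_halving_dt_leaves_settled_pattern_unchanged(self):
        # identical noise field, twice the time resolution: the settled
        # pattern must agree to <1% in relative L2
        results = []
        for dt in (1e-3, 5e-4):
            cfg = _cfg(a=24.0, nx=80, ny=80, dx=0.25, dt=dt, noise_sd=0.01,
                       seed=5, stages=[ProtocolStage(duration=120.0)],
                       snapshot_interval=60.0)
            res = pde.run_protocol(cfg, classify=False)
            results.append(res.snapshots[-1].u)
        diff = np.linalg.norm(results[0] - results[1])
        assert diff / np.linalg.norm(results[1] - results[1].mean()) < 0.01

    def test_grid_spacing_choice_preserves_classification(self):
        # quarter vs half resolution of the same 16x16 physical domain
        reports = []
        for nx, dx in ((128, 0.125), (64, 0.25)):
            cfg = _cfg(a=24.0, nx=nx, ny=nx, dx=dx, dt=1e-3, noise_sd=0.01,
                       seed=3, stages=[ProtocolStage(duration=150.0)],
                       snapshot_interval=75.0)
            reports.append(pde.run_protocol(cfg).stage_summaries[0].report)
        coarse_bin = max(r.k_bin for r in reports)
        assert reports[0].is_patterned and reports[1].is_patterned
        assert abs(reports[0].dominant_k - reports[1].dominant_k) <= coarse_bin


class TestProtocol:
    def test_stage_continuity_and_snapshot_cadence(self):
        cfg = _cfg(a=24.0, noise_sd=0.01, seed=2, dt=1e-3,
                   stages=[ProtocolStage(duration=2.0),
                           ProtocolStage(duration=2.0,
                                         forcing=ForcingParams(A=2.0, T=1.0))],
                   snapshot_interval=1.0)
        res = pde.run_protocol(cfg)
        assert len(res.stage_summaries) == 2
        assert res.stage_summaries[0].t_end == pytest.approx(
            res.stage_summaries[1].t_start)
        times = [s.t for s in res.snapshots]
        assert times == sorted(times)
        assert res.snapshots[-1].t == pytest.approx(4.0, abs=1e-6)

    def test_forcing_phase_restarts_each_stage(self):
        # two protocols whose first stages differ only in duration must
        # produce identical forced stages when started from the same state
        base = dict(nx=24, ny=24, dx=0.25, dt=1e-3, noise_sd=0.0, seed=0)
        forced = ProtocolStage(duration=1.0, forcing=ForcingParams(A=6.0, T=1.0))
        outs = []
        for settle in (1.0, 1.5):
            cfg = _cfg(a=24.0, stages=[ProtocolStage(duration=settle), forced],
                       **base)
            u0, v0 = steady_state(cfg.params)
            # start on the homogeneous steady state: the settle stage is
            # then a no-op of either length
            res_state = pde.FieldState(u=np.full((24, 24), u0),
                                       v=np.full((24, 24), v0), t=0.0)
            factors = pde._factors(cfg)
            n_settle = round(settle / cfg.dt)
            s = pde._advance(res_state, cfg, cfg.stages[0], n_settle, 0.0,
                             0, factors)
            s = pde._advance(s, cfg, cfg.stages[1], round(1.0 / cfg.dt), 0.0,
                             n_settle % 2, factors)
            outs.append(s.u.copy())
        assert outs[0] == pytest.approx(outs[1], abs=1e-9)
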