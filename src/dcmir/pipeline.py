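"""End-to-end orchestration: simulate → tfr → fit → bms → stats → car.

Each stage reads the previous stage's files from the run directory, writes
its outputs plus a JSON provenance block (config hash, master seed, package
version), and is skipped on re-run when its provenance matches the current
configuration — so a completed directory is idempotent and any stage can be
recomputed with ``overwrite``.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dcmir import io
from dcmir._exceptions import ParameterError
from dcmir.bms import exceedance, rfx_bms
from dcmir.car import car_table, paired_car_test
from dcmir.coupling_stats import (
    coupling_to_frequency,
    paired_permutation_test,
    smooth_map,
    spearman_link,
)
from dcmir.dcm import (
    build_constraints,
    enumerate_model_space,
    estimate_noise_variance,
    invert,
)
from dcmir.synthgen import (
    SimConfig,
    make_input_waveform,
    simulate_cohort_spectra,
    simulate_cohort_trials,
    simulate_current_density,
)
from dcmir.tfr import average_baseline_crop, fit_modes, morlet_power, project_modes

STAGES = ("simulate", "tfr", "fit", "bms", "stats", "car")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    level: str = "trials"  # "trials" (full chain) or "spectra" (fast)
    n_subjects: int = 8
    n_trials: int = 48
    fs: float = 256.0
    snr_db: float = 10.0
    freq_lo: float = 4.0
    freq_hi: float = 48.0
    freq_step: float = 1.0
    K: int = 4
    prior_var: float = 1.0
    alpha: float = 0.05
    task: str = "open"
    true_model: int = 12
    wavelet_number: int = 7
    session_effect: list = field(default_factory=list)
    car_ratios_pre: dict = field(
        default_factory=lambda: {
            "iM1S1": 0.30, "cM1S1": 0.30, "iSMA-PM": 0.20, "cSMA-PM": 0.20,
        }
    )
    car_ratios_post: dict = field(
        default_factory=lambda: {
            "iM1S1": 0.35, "cM1S1": 0.25, "iSMA-PM": 0.20, "cSMA-PM": 0.20,
        }
    )
    car_noise_sd: float = 0.1
    stages: tuple = STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def freq_grid(self) -> np.ndarray:
        return np.arange(self.freq_lo, self.freq_hi + self.freq_step / 2,
                         self.freq_step)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_subjects=self.n_subjects,
            n_trials=self.n_trials,
            fs=self.fs,
            snr_db=self.snr_db,
            seed=self.seed,
            freq_grid=self.freq_grid(),
            session_effect=[tuple(e) for e in self.session_effect],
        )

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("stages")  # stage selection does not change the results
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _provenance(config: RunConfig, stage: str) -> dict:
    from dcmir import __version__

    return {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def _stage_done(config: RunConfig, run_dir: Path, stage: str) -> bool:
    prov = run_dir / f"provenance_{stage}.json"
    if not prov.exists():
        return False
    try:
        return io.load_json(prov)["config_hash"] == config.config_hash()
    except Exception:
        return False


def _key(labels: dict) -> str:
    return f"s{labels['subject']}_{labels['session']}"


def run_pipeline(config: RunConfig, overwrite: bool = False,
                 log=print) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    for stage in config.stages:
        if stage not in STAGES:
            raise ParameterError(f"unknown stage {stage!r}")
        if not overwrite and _stage_done(config, run_dir, stage):
            log(f"[{stage}] up to date, skipping")
            continue
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, run_dir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        io.save_json(run_dir / f"provenance_{stage}.json",
                     _provenance(config, stage))
        log(f"[{stage}] done in {time.time() - t0:.1f}s")
    return run_dir


def stage_simulate(config: RunConfig, run_dir: Path) -> None:
    sim = config.sim_config()
    space = enumerate_model_space()
    spec = space[config.true_model - 1]
    if config.level == "trials":
        trial_sets, truths = simulate_cohort_trials(
            spec, sim, task=config.task
        )
        path = run_dir / "trials.h5"
        if path.exists():
            path.unlink()
        for ts in trial_sets:
            io.save_trialset(path, ts, name=_key(ts.labels))
    else:
        specs, truths = simulate_cohort_spectra(spec, sim, task=config.task)
        path = run_dir / "spectra_sim.h5"
        if path.exists():
            path.unlink()
        for sp in specs:
            io.save_spectrogram(path, sp, name=_key(sp.labels))
    io.save_json(
        run_dir / "groundtruth.json",
        {
            "true_model": config.true_model,
            "subjects": {
                str(s): {"model_id": gt.model_id, "stable": bool(gt.stable)}
                for s, gt in truths.items()
            },
        },
    )


def stage_tfr(config: RunConfig, run_dir: Path) -> None:
    out = run_dir / "spectra.h5"
    if out.exists():
        out.unlink()
    specs = []
    if config.level == "trials":
        src = run_dir / "trials.h5"
        for name in io.list_groups(src):
            trials = io.load_trialset(src, name)
            stack = morlet_power(trials, config.freq_grid(),
                                 config.wavelet_number)
            specs.append(average_baseline_crop(stack))
    else:
        src = run_dir / "spectra_sim.h5"
        for name in io.list_groups(src):
            specs.append(io.load_spectrogram(src, name))
    for sp in specs:
        io.save_spectrogram(out, sp, name=_key(sp.labels))
    basis = fit_modes(specs, K=config.K)
    io.save_basis(run_dir / "basis.h5", basis)


def _input_waveform(config: RunConfig):
    sim = config.sim_config()
    return make_input_waveform(sim.sim_t_grid())


def stage_fit(config: RunConfig, run_dir: Path) -> None:
    basis = io.load_basis(run_dir / "basis.h5")
    space = enumerate_model_space()
    wave = _input_waveform(config)
    full = space[-1]
    rows = []
    fits_path = run_dir / "fits.h5"
    if fits_path.exists():
        fits_path.unlink()
    import h5py

    with h5py.File(fits_path, "a") as f:
        for name in io.list_groups(run_dir / "spectra.h5"):
            sp = io.load_spectrogram(run_dir / "spectra.h5", name)
            series = project_modes(sp, basis)
            nv = estimate_noise_variance(
                series, wave.u, build_constraints(full, basis)
            )
            for model in space:
                fit = invert(series, wave.u, model, basis,
                             prior_var=config.prior_var, noise_var=nv)
                g = f.create_group(f"{name}_m{model.model_id}")
                g.create_dataset("A", data=fit.A)
                g.create_dataset("C", data=fit.C)
                rows.append(
                    {
                        "subject": sp.labels["subject"],
                        "session": sp.labels["session"],
                        "task": sp.labels.get("task", config.task),
                        "model": model.model_id,
                        "log_evidence": fit.log_evidence,
                        "variance_explained": fit.variance_explained,
                    }
                )
    pd.DataFrame(rows).to_csv(run_dir / "evidence.csv", index=False)


def stage_bms(config: RunConfig, run_dir: Path) -> None:
    ev = pd.read_csv(run_dir / "evidence.csv")
    # sum evidence over sessions per subject (independent data segments)
    summed = (
        ev.groupby(["subject", "model"])["log_evidence"].sum().unstack("model")
    )
    L = summed.to_numpy()
    result = rfx_bms(L)
    xp = exceedance(result, n_samples=200_000, seed=config.seed)
    io.save_json(
        run_dir / "bms.json",
        {
            "models": [int(m) for m in summed.columns],
            "alpha": result.alpha,
            "expected_prob": result.expected_prob,
            "exceedance_prob": xp,
            "winning_model": int(summed.columns[result.winning_model]),
            "n_samples": result.n_samples,
            "seed": config.seed,
        },
    )


def stage_stats(config: RunConfig, run_dir: Path) -> None:
    basis = io.load_basis(run_dir / "basis.h5")
    bms_info = io.load_json(run_dir / "bms.json")
    winner = bms_info["winning_model"]
    space = enumerate_model_space()
    spec = space[winner - 1]
    import h5py

    K = basis.K
    regions = spec.regions
    # collect per-subject smoothed maps per connection and session
    maps: dict[tuple[str, str], dict[str, list]] = {}
    with h5py.File(run_dir / "fits.h5", "r") as f:
        names = sorted(
            n for n in f.keys() if n.endswith(f"_m{winner}")
        )
        for name in names:
            A = f[name]["A"][()]
            subject = int(name.split("_")[0][1:])
            session = name.split("_")[1]
            from dcmir.dcm import DCMFit

            fit = DCMFit(
                model_id=winner, A=A, C=f[name]["C"][()],
                A_var=np.zeros_like(A), C_var=np.zeros(A.shape[0]),
                log_evidence=0.0, variance_explained=0.0,
                noise_var=np.zeros(A.shape[0]), K=K, regions=regions,
                labels={"subject": subject, "session": session},
            )
            for conn, cmap in coupling_to_frequency(fit, basis).items():
                maps.setdefault(conn, {}).setdefault(session, []).append(
                    smooth_map(cmap)
                )
    rows = []
    for conn, by_session in sorted(maps.items()):
        pre = sorted(by_session.get("pre", []),
                     key=lambda m: m.labels["subject"])
        post = sorted(by_session.get("post", []),
                      key=lambda m: m.labels["subject"])
        if not pre or not post:
            continue
        stat = paired_permutation_test(pre, post, alpha=config.alpha,
                                       seed=config.seed)
        fo, fi = np.nonzero(stat.significant)
        for a, b in zip(fo, fi):
            rows.append(
                {
                    "source": conn[0],
                    "target": conn[1],
                    "f_out_hz": stat.freq_grid[a],
                    "f_in_hz": stat.freq_grid[b],
                    "t": stat.t_values[a, b],
                    "p_fwe": stat.p_fwe[a, b],
                }
            )
    pd.DataFrame(
        rows, columns=["source", "target", "f_out_hz", "f_in_hz", "t", "p_fwe"]
    ).to_csv(run_dir / "significant_couplings.csv", index=False)


def stage_car(config: RunConfig, run_dir: Path) -> None:
    maps = []
    for session, ratios in (("pre", config.car_ratios_pre),
                            ("post", config.car_ratios_post)):
        nodes = {roi: 100 for roi in ratios}
        maps += simulate_current_density(
            roi_partition=nodes,
            target_ratios=ratios,
            noise_sd=config.car_noise_sd,
            n_subjects=config.n_subjects,
            seed=config.seed + (1 if session == "post" else 0),
            session=session,
            task=config.task,
        )
    table = car_table(maps)
    table.to_csv(run_dir / "car_table.csv", index=False)
    tests = {}
    for roi in config.car_ratios_pre:
        res = paired_car_test(table, roi, task=config.task)
        tests[roi] = {
            "t": res.t, "p": res.p, "mean_delta": res.mean_delta,
            "p_signflip": res.p_signflip, "n": res.n,
            "degenerate_variance": res.degenerate_variance,
        }
    # link CAR changes to coupling changes at the strongest pre/post pair
    link = None
    sig = pd.read_csv(run_dir / "significant_couplings.csv") if (
        run_dir / "significant_couplings.csv"
    ).exists() else pd.DataFrame()
    pivot = table[table["roi"] == "cM1S1"].pivot_table(
        index="subject", columns="session", values="car"
    )
    if {"pre", "post"} <= set(pivot.columns) and len(sig):
        delta_car = (pivot["post"] - pivot["pre"]).to_numpy()
        top = sig.iloc[sig["t"].abs().idxmax()]
        basis = io.load_basis(run_dir / "basis.h5")
        fgrid = basis.freq_grid
        a = int(np.argmin(np.abs(fgrid - top["f_out_hz"])))
        b = int(np.argmin(np.abs(fgrid - top["f_in_hz"])))
        import h5py

        space = enumerate_model_space()
        winner = io.load_json(run_dir / "bms.json")["winning_model"]
        spec = space[winner - 1]
        i = spec.regions.index(top["target"])
        j = spec.regions.index(top["source"])
        K = basis.K
        deltas = []
        with h5py.File(run_dir / "fits.h5", "r") as f:
            for s in range(config.n_subjects):
                vals = {}
                for session in ("pre", "post"):
                    A = f[f"s{s}_{session}_m{winner}"]["A"][()]
                    block = A[i * K : (i + 1) * K, j * K : (j + 1) * K]
                    vals[session] = float(
                        basis.V[a] @ block @ basis.V[b]
                    )
                deltas.append(vals["post"] - vals["pre"])
        rho, p = spearman_link(delta_car, np.array(deltas))
        link = {
            "roi": "cM1S1",
            "connection": [top["source"], top["target"]],
            "f_out_hz": float(top["f_out_hz"]),
            "f_in_hz": float(top["f_in_hz"]),
            "rho": rho,
            "p": p,
        }
    io.save_json(run_dir / "car_tests.json",
                 {"tests": tests, "spearman_link": link})


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "tfr": stage_tfr,
    "fit": stage_fit,
    "bms": stage_bms,
    "stats": stage_stats,
    "car": stage_car,
}


def validate_io(path: str | Path) -> list[str]:
    """Check a run directory's files against the expected schemas.

    Returns a list of human-readable violations (empty when clean).
    Unreadable files are listed, not fatal.
    """
    import h5py

    run_dir = Path(path)
    violations: list[str] = []
    for h5name in ("trials.h5", "spectra.h5", "spectra_sim.h5"):
        p = run_dir / h5name
        if not p.exists():
            continue
        try:
            with h5py.File(p, "r") as f:
                for name, g in f.items():
                    if "power" in g:
                        if g["power"].shape[1] != g["freq_grid"].shape[0]:
                            violations.append(
                                f"{h5name}:{name}: power/freq_grid mismatch"
                            )
                        if g["power"].shape[2] != g["t_grid"].shape[0]:
                            violations.append(
                                f"{h5name}:{name}: power/t_grid mismatch"
                            )
                    if "data" in g and float(g.attrs.get("fs", 0)) <= 0:
                        violations.append(f"{h5name}:{name}: nonpositive fs")
        except OSError as exc:
            violations.append(f"{h5name}: unreadable ({exc})")
    ev = run_dir / "evidence.csv"
    if ev.exists():
        df = pd.read_csv(ev)
        if not np.all(np.isfinite(df["log_evidence"])):
            violations.append("evidence.csv: non-finite log evidence")
    for csvname in list(run_dir.glob("current_density*.csv")):
        df = pd.read_csv(csvname)
        bad = df.index[df["strength"] < 0].tolist()
        for row in bad:
            violations.append(f"{csvname.name}: negative strength at row {row}")
    car = run_dir / "car_table.csv"
    if car.exists():
        df = pd.read_csv(car)
        sums = df.groupby(["subject", "session", "task"])["car"].sum()
        for key, s in sums.items():
            if abs(s - 1.0) > 1e-8:
                violations.append(f"car_table.csv: CARs sum to {s} for {key}")
    return violations
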