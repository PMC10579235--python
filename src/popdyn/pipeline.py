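"""Pipeline orchestration: simulate -> rates -> geometry -> downstream
analyses from a single config, with deterministic per-stage seeding.

The config is a plain mapping (typically loaded from YAML): a global
``seed``, an ``out_dir``, either a ``bundle`` path or a ``simulation``
block, and an ordered ``stages`` list with optional per-stage parameter
blocks.  Each stage receives its own random stream spawned from
``(seed, stage_name)`` so adding or removing a stage never shifts another
stage's draws.  A JSON manifest records inputs, parameters, per-stage
seeds and SHA-256 hashes of every output file; identical config + seed
yields identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoders, geometry, kinet, overlap, selectivity
from .rates import Kernel, align_and_rate, compute_rate_tensor
from .session import make_rt_bins, read_session
from .simulate import SimulationConfig, simulate_session, write_simulated_bundle

__all__ = ["run_pipeline", "load_config", "KNOWN_STAGES", "stage_seed"]


def load_config(path: str | Path) -> dict:
    """Load a pipeline config from a YAML file."""
    import yaml

    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg

KNOWN_STAGES = (
    "simulate",
    "behavior",
    "rates",
    "pca",
    "kinet",
    "cs",
    "decode",
    "lds",
    "rrr",
    "overlap",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: global seed mixed with the stage name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages and return the run manifest."""
    stages = list(config.get("stages", KNOWN_STAGES))
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s) {unknown}; known: {list(KNOWN_STAGES)}")
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "popdyn_run"))
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "seed": seed,
        "stages": [],
        "outputs": {},
        "parameters": {k: v for k, v in config.items() if k not in ("stages",)},
    }
    ctx: dict = {}

    def record(stage: str, files: list[Path], t0: float, **info) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": stage_seed(seed, stage),
                "elapsed_s": round(time.perf_counter() - t0, 3),
                **info,
            }
        )
        for f in files:
            manifest["outputs"][str(f.relative_to(out_dir))] = _sha256(f)

    for stage in stages:
        t0 = time.perf_counter()
        params = dict(config.get(stage, {}))
        rng = np.random.default_rng(stage_seed(seed, stage))
        try:
            if stage == "simulate":
                sim_cfg = SimulationConfig(
                    **{**config.get("simulation", {}), "seed": stage_seed(seed, stage)}
                )
                bundle = out_dir / "session_bundle"
                ctx["session"] = write_simulated_bundle(sim_cfg, bundle)
                ctx["sim_config"] = sim_cfg
                record(
                    stage,
                    [bundle / f for f in ("trials.csv", "units.csv", "spikes.csv")],
                    t0,
                    n_trials=ctx["session"].n_trials,
                    n_units=ctx["session"].n_units,
                )
                continue

            if "session" not in ctx:
                bundle = config.get("bundle")
                if bundle is None:
                    raise ValueError("no session available: provide 'bundle' or run simulate")
                ctx["session"] = read_session(bundle)
            session = ctx["session"]

            if stage == "behavior":
                trials = session.trials
                coh = np.array([abs(t.signed_coherence) for t in trials])
                levels = np.unique(coh)
                pcorr = np.array(
                    [np.mean([t.correct for t in trials if abs(t.signed_coherence) == c]) for c in levels]
                )
                fit = behavior.fit_weibull(levels, pcorr)
                chrono = behavior.rt_coherence_r2(session.rts(), coh)
                seq = behavior.post_outcome_rt_comparison(trials)
                f = out_dir / "psychometric_fit.csv"
                pd.DataFrame(
                    [{"alpha": fit.alpha, "gamma_slope": fit.gamma_slope, "r2": fit.r2,
                      "rt_coherence_r2": chrono}]
                ).to_csv(f, index=False)
                g = out_dir / "outcome_sequences.csv"
                pd.DataFrame(
                    [{"ec_median_rt": seq.ec_median, "cc_median_rt": seq.cc_median,
                      "n_ec": len(seq.ec_rts), "n_cc": len(seq.cc_rts),
                      "ranksum_p": seq.p_value}]
                ).to_csv(g, index=False)
                record(stage, [f, g], t0)

            elif stage == "rates":
                from .io_h5 import save_rate_tensor

                kern = Kernel(**params.get("kernel", {})) if params.get("kernel") else None
                ctx["rt_tensor"] = compute_rate_tensor(
                    session, grouping=params.get("grouping", "rt"),
                    window=tuple(params.get("window_ms", (-600.0, 1200.0))),
                    kernel=kern,
                )
                f = save_rate_tensor(ctx["rt_tensor"], out_dir / "rate_tensor.h5")
                record(stage, [f], t0, grouping=params.get("grouping", "rt"))

            elif stage == "pca":
                tensor = ctx["rt_tensor"]
                pcs = geometry.fit_pca_tensor(tensor)
                ctx["pcs"] = pcs
                n_dims = int(params.get("n_dims", 6))
                trajset = geometry.project(tensor, pcs, n_dims=n_dims)
                trajset.reference_index = len(tensor.condition_labels) // 2
                ctx["trajset"] = trajset
                from .io_h5 import save_pcspace

                f = out_dir / "explained_variance.csv"
                pd.DataFrame(
                    {"component": np.arange(1, len(pcs.eigenvalues) + 1),
                     "eigenvalue": pcs.eigenvalues,
                     "explained_fraction": pcs.explained_variance_ratio}
                ).to_csv(f, index=False)
                g = save_pcspace(pcs, out_dir / "pcspace.h5")
                record(stage, [f, g], t0, n_dims=n_dims)

            elif stage == "kinet":
                res = kinet.kinet_analyze(ctx["trajset"])
                rows = []
                for i in range(res.signed_distance.shape[0]):
                    for j, tref in enumerate(res.ref_times):
                        rows.append(
                            {"trajectory": i, "ref_time_ms": tref,
                             "t_ref_ms": res.t_ref[i, j],
                             "signed_distance": res.signed_distance[i, j]}
                        )
                f = out_dir / "kinet.csv"
                pd.DataFrame(rows).to_csv(f, index=False)
                speed = kinet.scalar_speed(ctx["trajset"])
                g = out_dir / "prestim_speed.csv"
                pd.DataFrame(
                    {"condition": speed.condition_labels, "prestim_speed": speed.prestim_mean}
                ).to_csv(g, index=False)
                record(stage, [f, g], t0)

            elif stage == "cs":
                trajset = ctx["trajset"]
                rows = []
                labels = [lab for ch, lab in trajset.labels if ch == "left"]
                for lab in labels:
                    li = trajset.labels.index(("left", lab))
                    ri = trajset.labels.index(("right", lab))
                    curve = selectivity.cs_curve(
                        trajset.trajectories[li], trajset.trajectories[ri],
                        trajset.times[li],
                    )
                    fit = selectivity.fit_piecewise_cs(curve)
                    rows.append({"condition": lab, "baseline": fit.b, "slope": fit.m,
                                 "latency_ms": fit.t_latency, "flat": fit.flat})
                f = out_dir / "piecewise_fits.csv"
                pd.DataFrame(rows).to_csv(f, index=False)
                record(stage, [f], t0)

            elif stage == "decode":
                units = params.get("units")
                if units is None and session.n_units > 50:
                    units = rng.choice(session.n_units, 50, replace=False)
                window = tuple(params.get("window_ms", (-400.0, 0.0)))
                n_shuffles = int(params.get("n_shuffles", 100))
                rt_res = decoders.rt_decoder(
                    session, bin_ms=float(params.get("rt_bin_ms", 100.0)),
                    window=window, n_shuffles=n_shuffles, rng=rng, units=units,
                )
                ch_res = decoders.choice_decoder(
                    session, bin_ms=float(params.get("choice_bin_ms", window[1] - window[0])),
                    window=window, n_shuffles=n_shuffles, rng=rng, units=units,
                )
                f = out_dir / "decoder_results.csv"
                rows = [
                    {"analysis": "rt_r2", "bin_start_ms": b, "metric": v,
                     "null_p99": hi, "null_p01": lo}
                    for b, v, hi, lo in zip(
                        rt_res.bin_starts, rt_res.r2, rt_res.null_p99, rt_res.null_p01
                    )
                ] + [
                    {"analysis": "choice_accuracy", "bin_start_ms": b, "metric": v,
                     "null_p99": hi, "null_p01": lo}
                    for b, v, hi, lo in zip(
                        ch_res.bin_starts, ch_res.accuracy, ch_res.null_p99, ch_res.null_p01
                    )
                ]
                pd.DataFrame(rows).to_csv(f, index=False)
                record(stage, [f], t0)

            elif stage == "lds":
                from .dynamics import fit_lds, latents_from_counts

                window = tuple(params.get("window_ms", (-600.0, 0.0)))
                counts, _ = decoders.bin_spike_counts(session, bin_ms=50.0, window=window)
                left = np.flatnonzero(session.choices() == "left")
                latents = latents_from_counts(counts[left], int(params.get("latent_dim", 4)))
                fit = fit_lds(latents, epoch=params.get("epoch", "prestimulus"))
                f = out_dir / "lds_fit.csv"
                pd.DataFrame(
                    [{"dim": fit.latent_dim, "epoch": fit.epoch, "cv_r2": fit.cv_r2}]
                ).to_csv(f, index=False)
                record(stage, [f], t0)

            elif stage == "rrr":
                from .dynamics import fit_rrr

                pre_w = tuple(params.get("pre_window_ms", (-400.0, 0.0)))
                post_w = tuple(params.get("post_window_ms", (100.0, 500.0)))
                pre, _ = decoders.bin_spike_counts(session, bin_ms=pre_w[1] - pre_w[0], window=pre_w)
                post, _ = decoders.bin_spike_counts(session, bin_ms=post_w[1] - post_w[0], window=post_w)
                choice = (session.choices() == "right").astype(float)
                coh = np.array([abs(t.signed_coherence) for t in session.trials])
                X = np.column_stack([pre[:, 0, :], choice, coh])
                Y = post[:, 0, :]
                fit = fit_rrr(X, Y, ranks=params.get("ranks"), rng=rng, ridge=1e-6)
                f = out_dir / "rrr_fit.csv"
                pd.DataFrame(
                    {"rank": fit.candidate_ranks, "val_mse": fit.val_mse}
                ).assign(chosen_rank=fit.rank, cv_r2=fit.cv_r2).to_csv(f, index=False)
                record(stage, [f], t0)

            elif stage == "overlap":
                tensor_rt = ctx.get("rt_tensor") or compute_rate_tensor(session, grouping="rt")
                tensor_out = compute_rate_tensor(session, grouping="outcome")
                mat_rt, _, _, _ = geometry.soft_normalize_stack(tensor_rt)
                pcs_rt = ctx.get("pcs") or geometry.fit_pca(mat_rt)
                pcs_out = geometry.fit_pca_tensor(tensor_out)
                cov_rt = np.cov(mat_rt, rowvar=False)
                res = overlap.alignment_index(
                    cov_rt, pcs_out.loadings[:, :6], pcs_rt.eigenvalues
                )
                f = out_dir / "alignment.csv"
                pd.DataFrame(
                    [{"alignment_index": res.A, "n_dims": res.n_dims_numerator,
                      "captured_variance": res.captured_variance,
                      "total_variance": res.total_variance}]
                ).to_csv(f, index=False)
                record(stage, [f], t0)

        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
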