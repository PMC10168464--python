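"""Runnable validation studies for the DDcTV FL-ADMM solver.

Four studies, desk-scale versions of the usual validation protocol for a
new iterative reconstruction algorithm:

* ``inverse_crime``  — same-projector noiseless data from a Shepp-Logan
  phantom, DDcTV with an exact data constraint (eps = 0): the solver must
  drive RMSE below 1e-4, the conventional sign that the imaging model,
  the optimization model, the algorithm and the implementation are all
  correct.
* ``beta_sweep``     — convergence rate as a function of the penalty beta
  over {0.01, 0.1, 1, 10, 100} at a fixed outer budget.
* ``inner_sweep``    — convergence rate as a function of the inner
  (image-step) iteration count.
* ``cp_compare``     — DDcTV FL-ADMM against the Chambolle–Pock baseline
  across projection counts, reporting RMSE/SSIM/PSNR per view count.

Default problem sizes are 64 x 64 with desk-scale iteration budgets so a
full study finishes in minutes on one CPU; every run is deterministic
given its spec (the only randomness is the seeded power-method start
vector).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import ImageGrid, ScanGeometry
from .metrics import psnr, rmse, ssim
from .phantoms import PhantomSpec, make_phantom
from .projector import RadonTransform
from .solvers import CPConfig, SolverConfig, cp_ddctv, solve_ddctv

__all__ = ["StudySpec", "run_study", "STUDIES"]

STUDIES = ("inverse_crime", "beta_sweep", "inner_sweep", "cp_compare")


# per-study defaults: (phantom, n_views, sweep, n_outer, beta)
_DEFAULTS = {
    "inverse_crime": ("shepp_logan", 64, (), 4000, 1.0),
    "beta_sweep": ("forbild_like", 25, (0.01, 0.1, 1.0, 10.0, 100.0), 500, 10.0),
    "inner_sweep": ("forbild_like", 25, (1, 50, 100, 150, 200), 300, 10.0),
    "cp_compare": ("blocks", 50, (20, 40, 60, 80, 100), 400, 10.0),
}


@dataclass
class StudySpec:
    """One validation study: which protocol, at what scale, over what sweep.

    Unset fields (``None`` / empty sweep) take the per-study defaults in
    ``_DEFAULTS``; for ``cp_compare`` the sweep values are view counts and
    ``n_views`` is unused.
    """

    study: str
    size: int = 64
    n_views: int | None = None
    phantom: str | None = None
    sweep: tuple = ()
    n_outer: int | None = None
    n_inner: int = 50
    beta: float | None = None
    seed: int = 0
    rmse_threshold: float = 1e-4  # inverse_crime success level
    cp_n_iter: int = 35000
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.study not in STUDIES:
            raise ValueError(f"unknown study {self.study!r}; choose from {STUDIES}")
        phantom, n_views, sweep, n_outer, beta = _DEFAULTS[self.study]
        self.phantom = self.phantom or phantom
        self.n_views = self.n_views or n_views
        self.sweep = tuple(self.sweep) or sweep
        self.n_outer = self.n_outer or n_outer
        self.beta = beta if self.beta is None else self.beta
        if not self.sweep and self.study != "inverse_crime":
            raise ValueError("sweep values must be non-empty")
        if self.n_outer < 1 or self.n_inner < 1:
            raise ValueError("iteration budgets must be >= 1")


def _problem(spec: StudySpec, n_views: int | None = None):
    n = spec.size
    grid = ImageGrid(n, n)
    geom = ScanGeometry(n, n_views or spec.n_views)
    truth = make_phantom(PhantomSpec(spec.phantom, (n, n)))
    A = RadonTransform(grid, geom)
    return grid, geom, truth, A, A.apply(truth)


def _flush(spec: StudySpec, name: str, obj) -> None:
    if spec.out_dir is None:
        return
    out = Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(out / f"{name}.csv", index=False, float_format="%.17g")
    else:  # image
        from .io import write_image

        write_image(out / f"{name}.tif", obj)


def _run_inverse_crime(spec: StudySpec) -> dict:
    _, _, truth, A, g = _problem(spec)
    cfg = SolverConfig(
        model="ddctv",
        n_outer=spec.n_outer,
        n_inner=spec.n_inner,
        beta=spec.beta,
        epsilon=0.0,
        seed=spec.seed,
        early_stop_tol=spec.rmse_threshold,
        log_every=1,
    )
    u, record = solve_ddctv(g, A, cfg, truth=truth)
    first_hit = record.first_iter_below(spec.rmse_threshold)
    summary = pd.DataFrame(
        [
            {
                "final_rmse": record.rmse[-1],
                "final_ssim": ssim(u, truth),
                "final_psnr": psnr(u, truth, cap=200.0),
                "first_hit_iter": np.nan if first_hit is None else first_hit,
                "threshold": spec.rmse_threshold,
            }
        ]
    )
    _flush(spec, "inverse_crime_convergence", record.to_dataframe())
    _flush(spec, "inverse_crime_summary", summary)
    _flush(spec, "inverse_crime_recon", u)
    return {"summary": summary, "records": {"run": record}, "images": {"run": u}, "truth": truth}


def _run_sweep(spec: StudySpec) -> dict:
    """Shared driver for beta_sweep and inner_sweep (fixed-budget runs)."""
    _, _, truth, A, g = _problem(spec)
    rows, records, images = [], {}, {}
    for value in spec.sweep:
        if spec.study == "beta_sweep":
            beta, n_inner = float(value), spec.n_inner
        else:
            beta, n_inner = spec.beta, int(value)
        cfg = SolverConfig(
            model="ddctv",
            n_outer=spec.n_outer,
            n_inner=n_inner,
            beta=beta,
            epsilon=0.0,
            seed=spec.seed,
            log_every=max(1, spec.n_outer // 100),
        )
        u, record = solve_ddctv(g, A, cfg, truth=truth)
        records[value] = record
        images[value] = u
        rows.append(
            {
                "value": value,
                "final_rmse": record.rmse[-1],
                "final_ssim": ssim(u, truth),
                "final_psnr": psnr(u, truth, cap=200.0),
                "first_hit_iter": record.first_iter_below(spec.rmse_threshold) or np.nan,
            }
        )
        _flush(spec, f"{spec.study}_convergence_{value}", record.to_dataframe())
    summary = pd.DataFrame(rows).sort_values("final_rmse").reset_index(drop=True)
    _flush(spec, f"{spec.study}_summary", summary)
    return {"summary": summary, "records": records, "images": images, "truth": truth}


def _run_cp_compare(spec: StudySpec) -> dict:
    rows, records, images = [], {}, {}
    for n_views in spec.sweep:
        _, _, truth, A, g = _problem(spec, n_views=int(n_views))
        cfg = SolverConfig(
            model="ddctv",
            n_outer=spec.n_outer,
            n_inner=spec.n_inner,
            beta=spec.beta,
            epsilon=0.0,
            seed=spec.seed,
            log_every=spec.n_outer,
        )
        u_fl, rec_fl = solve_ddctv(g, A, cfg, truth=truth)
        cp_cfg = CPConfig(
            n_iter=spec.cp_n_iter, epsilon=0.0, seed=spec.seed, log_every=spec.cp_n_iter
        )
        u_cp, rec_cp = cp_ddctv(g, A, cp_cfg, truth=truth)
        records[n_views] = {"fladmm": rec_fl, "cp": rec_cp}
        images[n_views] = {"fladmm": u_fl, "cp": u_cp}
        rows.append(
            {
                "n_views": n_views,
                "rmse_fladmm": rmse(u_fl, truth),
                "rmse_cp": rmse(u_cp, truth),
                "ssim_fladmm": ssim(u_fl, truth),
                "ssim_cp": ssim(u_cp, truth),
                "psnr_fladmm": psnr(u_fl, truth, cap=200.0),
                "psnr_cp": psnr(u_cp, truth, cap=200.0),
            }
        )
        _flush(spec, f"cp_compare_partial_{n_views}", pd.DataFrame(rows))
    summary = pd.DataFrame(rows)
    _flush(spec, "cp_compare_summary", summary)
    return {"summary": summary, "records": records, "images": images, "truth": None}


def run_study(spec: StudySpec) -> dict:
    """Run one study; returns ``{"summary": DataFrame, "records": ..., "images": ...}``.

    With ``spec.out_dir`` set, per-run convergence CSVs, a summary CSV and
    reconstructed images are written there (partial results are flushed as
    each sweep value completes).
    """
    if spec.study == "inverse_crime":
        return _run_inverse_crime(spec)
    if spec.study in ("beta_sweep", "inner_sweep"):
        return _run_sweep(spec)
    return _run_cp_compare(spec)
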