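"""Curve files, run configuration, and the end-to-end pipeline.

Curve files are plain text: columns q (Å^-1), I(q), optionally sigma_I,
whitespace-separated, with ``#``-prefixed comment headers.  Configuration is
a single YAML document whose sections mirror the pipeline stages; unknown
keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigError, CurveParseError, OutOfRangeError, PipelineStageError
from .fitting import fit_shell_model
from .occlusion import (
    PhysicalConstants,
    build_efficiency_relation,
    estimate_encapsulated_concentration,
    rg_contrast_sweep,
)
from .shell_model import ScatteringCurve, Shell, ShellProfile, SizeDistribution
from .synthetic import CANONICAL_LAYERS, CANONICAL_MEAN_RADIUS, CANONICAL_SIGMA_FRACTION, NoiseModel, synth_curve
from .transforms import distance_distribution, guinier_fit

__all__ = [
    "read_curve",
    "write_curve",
    "RunConfig",
    "default_config",
    "load_config",
    "profile_from_config",
    "run_pipeline",
]

log = logging.getLogger("liposaxs")


def read_curve(path, q_unit: str = "1/angstrom") -> ScatteringCurve:
    """Load a scattering curve from a 2- or 3-column text file.

    ``#`` comment lines are preserved in ``curve.metadata["header"]``.  Rows
    with nonpositive q are dropped (with a logged count); ``q_unit`` may be
    ``"1/nm"`` to convert nm^-1 grids to Å^-1 on load.
    """
    path = Path(path)
    header: list[str] = []
    rows: list[tuple[float, ...]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("#"):
                header.append(text.lstrip("# ").rstrip())
                continue
            parts = text.split()
            if len(parts) < 2:
                raise CurveParseError(f"{path}:{lineno}: expected >= 2 columns, got {len(parts)}")
            try:
                rows.append(tuple(float(p) for p in parts[:3]))
            except ValueError as exc:
                raise CurveParseError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise CurveParseError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    data = np.array([r[:ncol] for r in rows])
    if q_unit == "1/nm":
        data[:, 0] *= 0.1
    elif q_unit != "1/angstrom":
        raise ConfigError(f"unknown q unit {q_unit!r}")
    keep = data[:, 0] > 0
    dropped = int((~keep).sum())
    if dropped:
        log.warning("%s: dropped %d row(s) with nonpositive q", path, dropped)
    data = data[keep]
    order = np.argsort(data[:, 0])
    data = data[order]
    sigma = data[:, 2] if ncol >= 3 else None
    return ScatteringCurve(
        q=data[:, 0],
        intensity=data[:, 1],
        sigma=sigma,
        metadata={"header": header, "path": str(path)},
    )


def write_curve(curve: ScatteringCurve, path, comments: list[str] | None = None) -> None:
    """Write a curve as columns q, I[, sigma] with ``#`` header lines."""
    path = Path(path)
    cols = [curve.q, curve.intensity] + ([curve.sigma] if curve.sigma is not None else [])
    lines = []
    for c in comments or []:
        lines.append(f"# {c}")
    lines.append("# q[1/angstrom] intensity" + (" sigma" if curve.sigma is not None else ""))
    for row in zip(*cols):
        lines.append(" ".join(f"{v:.17e}" for v in row))
    path.write_text("\n".join(lines) + "\n")


# --- configuration ----------------------------------------------------------


def _canonical_model() -> dict:
    shells = [{"radius": None, "contrast": 0.0}]
    for name, thickness, contrast in CANONICAL_LAYERS:
        shells.append({"thickness": thickness, "contrast": contrast, "name": name})
    return {
        "shells": shells,
        "mean_radius": CANONICAL_MEAN_RADIUS,
        "sigma_percent": 100.0 * CANONICAL_SIGMA_FRACTION,
        "r_min": None,
    }


@dataclass
class RunConfig:
    """Validated pipeline configuration with out-of-the-box defaults."""

    model: dict = field(default_factory=_canonical_model)
    analysis: dict = field(
        default_factory=lambda: {
            "fit_q_max": 0.2,
            "guinier_qrg_max": 0.5,
            "pr_r_max": 2000.0,
            "pr_n_r": 2001,
            "taper": True,
            "extrapolate": True,
        }
    )
    occlusion: dict = field(
        default_factory=lambda: {
            "rho_water": 9.38,
            "rho_protein": 11.85,
            "v_bar": 0.73,
            "n_contrast": 27,
            "contrast_max": 2.6,
            "c_max": None,
            "n_concentration": 25,
            "rg_empty": None,
            "rg_filled": None,
        }
    )
    synth: dict = field(
        default_factory=lambda: {
            "q_min": 1.5e-4,
            "q_max": 0.3,
            "n_q": 2000,
            "noise_floor": 0.01,
            "noise_scale": 0.0,
            "seed": 0,
            "filled_core_contrast": 0.1,
            "q_unit": "1/angstrom",
        }
    )
    fit: dict = field(
        default_factory=lambda: {
            "enabled": False,
            "free": ["scale", "contrasts"],
            "n_radius": 151,
        }
    )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    """Load a YAML config, merging over defaults; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return merge_config(raw)


def merge_config(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg = RunConfig()
    sections = {f.name for f in dataclasses.fields(cfg)}
    unknown = set(raw) - sections
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    for name, value in raw.items():
        section = getattr(cfg, name)
        if not isinstance(value, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        if name == "model":
            bad = set(value) - set(section)
            if bad:
                raise ConfigError(f"unknown key(s) in model: {sorted(bad)}")
            section.update(value)
        else:
            bad = set(value) - set(section)
            if bad:
                raise ConfigError(f"unknown key(s) in {name}: {sorted(bad)}")
            section.update(value)
    return cfg


def profile_from_config(cfg: RunConfig) -> tuple[ShellProfile, SizeDistribution]:
    """Build the shell profile and size distribution from the model section.

    Each shell entry carries either ``radius`` (absolute outer boundary, Å)
    or ``thickness`` (Å, stacked on the previous boundary) plus ``contrast``;
    the first entry is the water pool.  A null pool radius means "whatever
    the mean radius leaves after the wall".
    """
    model = cfg.model
    entries = model["shells"]
    if not entries:
        raise ConfigError("model.shells must be non-empty")
    mean_radius = float(model["mean_radius"])
    wall = 0.0
    for e in entries[1:]:
        if "thickness" not in e:
            raise ConfigError("wall shells must specify thickness")
        wall += float(e["thickness"])
    pool_radius = entries[0].get("radius")
    if pool_radius is None:
        pool_radius = mean_radius - wall
    shells = [Shell(outer_semi_axis=float(pool_radius), contrast=float(entries[0]["contrast"]))]
    r = float(pool_radius)
    for e in entries[1:]:
        r += float(e["thickness"])
        shells.append(
            Shell(
                outer_semi_axis=r,
                contrast=float(e["contrast"]),
                axial_ratio=float(e.get("axial_ratio", 1.0)),
            )
        )
    r_min = model.get("r_min")
    if r_min is None:
        r_min = wall
    sigma = float(model["sigma_percent"]) / 100.0 * mean_radius
    dist = SizeDistribution(mean_radius=mean_radius, sigma=sigma, r_min=float(r_min))
    return ShellProfile(tuple(shells)), dist


# --- pipeline ---------------------------------------------------------------


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineStageError(name, exc) from exc

        return wrapped

    return deco


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run simulate -> p(r) -> Guinier -> (optional fit) -> occlusion estimate.

    Writes all tables plus a JSON report (versions, seed, parameters) under
    ``outdir`` and returns the result bundle.  Repeated runs with the same
    config and seed produce byte-identical tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    bundle: dict = {"config": cfg.as_dict(), "version": __version__}
    try:
        profile, dist = profile_from_config(cfg)
        s = cfg.synth
        noise = NoiseModel(floor=s["noise_floor"], scale=s["noise_scale"], seed=int(s["seed"]))
        q_grid = np.linspace(s["q_min"], s["q_max"], int(s["n_q"]))

        @_stage("simulate")
        def simulate():
            curves = {}
            for tag, core in [("empty", 0.0), ("filled", float(s["filled_core_contrast"]))]:
                curve = synth_curve(profile.with_core_contrast(core), dist, noise=noise, q_grid=q_grid)
                write_curve(curve, outdir / f"{tag}_curve.dat", comments=[f"synthetic {tag}-LUV curve, seed={s['seed']}"])
                curves[tag] = curve
            log.info("simulated empty and filled curves on %d q points", len(q_grid))
            return curves

        curves = simulate()
        bundle["curves"] = curves

        a = cfg.analysis

        @_stage("pr")
        def pr_stage():
            out = {}
            r_grid = np.linspace(0.0, a["pr_r_max"], int(a["pr_n_r"]))
            for tag, curve in curves.items():
                dd = distance_distribution(
                    curve, r_grid=r_grid, window=a["taper"], extrapolate=a["extrapolate"]
                )
                np.savetxt(
                    outdir / f"{tag}_pr.dat",
                    np.column_stack([dd.r, dd.p]),
                    header=f"p(r) of {tag} curve; peak={dd.peak_position:.4f} A, ripple_extent={dd.ripple_extent:.4f} A",
                )
                out[tag] = dd
                log.info("%s p(r): peak %.1f A, ripple extent %.1f A", tag, dd.peak_position, dd.ripple_extent)
            return out

        bundle["pr"] = pr_stage()

        @_stage("guinier")
        def guinier_stage():
            out = {}
            for tag, curve in curves.items():
                res = guinier_fit(curve, qrg_max=a["guinier_qrg_max"])
                out[tag] = res
                log.info("%s Guinier: Rg = %.1f +/- %.1f A", tag, res.rg, res.rg_stderr)
            return out

        guinier = guinier_stage()
        bundle["guinier"] = guinier

        if cfg.fit["enabled"]:

            @_stage("fit")
            def fit_stage():
                result = fit_shell_model(
                    curves["empty"],
                    profile,
                    dist,
                    free=tuple(cfg.fit["free"]),
                    q_max=a["fit_q_max"],
                    n_radius=int(cfg.fit["n_radius"]),
                )
                log.info("fit: R = %.4f, success=%s", result.reliability_r, result.success)
                return result

            bundle["fit"] = fit_stage()

        o = cfg.occlusion
        constants = PhysicalConstants(
            rho_water=o["rho_water"], rho_protein=o["rho_protein"], v_bar=o["v_bar"]
        )

        @_stage("occlusion")
        def occlusion_stage():
            contrasts = np.linspace(0.0, o["contrast_max"], int(o["n_contrast"]))
            sweep = rg_contrast_sweep(profile, dist, contrasts)
            np.savetxt(
                outdir / "contrast_sweep.dat",
                np.column_stack([sweep.contrasts, sweep.rg, sweep.peak_positions]),
                header="core_contrast Rg[A] pr_peak[A]",
            )
            if o["c_max"] is None:
                c_grid = None  # library default: quadratic grid up to pool saturation
            else:
                c_grid = np.linspace(0.0, o["c_max"], int(o["n_concentration"]))
            relation = build_efficiency_relation(profile, dist, constants, c_grid=c_grid)
            np.savetxt(
                outdir / "efficiency_relation.dat",
                np.column_stack([relation.concentration, relation.contrast, relation.rg, relation.decrement]),
                header="concentration[%w/v] core_contrast Rg[A] decrement_rate",
            )
            rg_empty = o["rg_empty"] or guinier["empty"].rg
            rg_filled = o["rg_filled"] or guinier["filled"].rg
            estimate = None
            if rg_filled <= rg_empty:
                try:
                    estimate = estimate_encapsulated_concentration(rg_empty, rg_filled, relation)
                    log.info("encapsulated concentration estimate: %.2f %% w/v", estimate)
                except OutOfRangeError as exc:
                    log.warning("estimate skipped: %s", exc)
            return {"sweep": sweep, "relation": relation, "estimate": estimate,
                    "rg_empty": rg_empty, "rg_filled": rg_filled}

        bundle["occlusion"] = occlusion_stage()

        report = {
            "version": __version__,
            "numpy": np.__version__,
            "seed": int(s["seed"]),
            "config": cfg.as_dict(),
            "guinier": {tag: {"rg": res.rg, "rg_stderr": res.rg_stderr} for tag, res in guinier.items()},
            "pr_peaks": {tag: dd.peak_position for tag, dd in bundle["pr"].items()},
            "estimate_percent_wv": bundle["occlusion"]["estimate"],
        }
        if "fit" in bundle:
            report["fit"] = {"reliability_r": bundle["fit"].reliability_r, "params": bundle["fit"].params}
        (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        return bundle
    finally:
        log.removeHandler(handler)
        handler.close()
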