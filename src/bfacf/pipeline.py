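"""Reproducible generate -> analyze -> excise pipeline and the sweep driver.

A sweep configuration lists (knot, triplet) combinations plus the shared
protocol parameters (confinement radius, target length, replicate count,
seed, fit range, contact weights).  :func:`run_sweep` generates each
ensemble, writes the conformations and ensemble curves, fits the log-log
slopes of the contact probability and the mean end-to-end distance, and
returns one table row per combination — the machine-readable twin of the
annealing-parameter table.  Every artifact lands under a run directory with
a JSON manifest capturing all parameters and seeds, so (config, seed) maps
to a bit-identical output tree.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .engine import AnnealingTriplet, derive_seed, generate_ensemble
from .observables import (
    DEFAULT_DIAGONAL_WEIGHT,
    DEFAULT_FIT_RANGE,
    bootstrap_slope,
    contact_curve,
    ensemble_average,
    fit_loglog_slope,
)
from .polygon import SphericalConfinement, write_conformations
from .seeds import KnotId

__all__ = ["SweepConfig", "Combination", "load_config", "run_sweep", "PROFILES"]

#: Named parameter profiles: reduced scales for tests and desk runs versus
#: the full-fidelity protocol (10^4 conformations of 4000 steps, 10^7
#: randomization proposals).
PROFILES: dict[str, dict[str, Any]] = {
    "smoke": {"target_length": 200, "n_conformations": 5, "randomize_steps": 20_000, "radius": 4.5},
    "desk": {"target_length": 4000, "n_conformations": 100, "randomize_steps": 100_000},
    "paper": {"target_length": 4000, "n_conformations": 10_000, "randomize_steps": 10_000_000},
}


@dataclass(frozen=True)
class Combination:
    knot: str
    triplet: tuple[float, float, float]

    def label(self) -> str:
        p = "_".join(f"{x:g}" for x in self.triplet)
        return f"{self.knot}__{p}"


@dataclass
class SweepConfig:
    combinations: list[Combination]
    radius: float = 10.5
    target_length: int = 4000
    n_conformations: int = 100
    seed: int = 1
    randomize_steps: int = 100_000
    s_min: int = DEFAULT_FIT_RANGE[0]
    s_max: int = DEFAULT_FIT_RANGE[1]
    diagonal_weight: float = DEFAULT_DIAGONAL_WEIGHT
    bootstrap: int = 1000
    out_dir: str = "runs/sweep"
    profile: str | None = None

    def __post_init__(self) -> None:
        if not self.combinations:
            raise ValueError("config must list at least one (knot, triplet) combination")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.target_length < 4 or self.target_length % 2:
            raise ValueError("target_length must be even and >= 4")
        if self.n_conformations < 1:
            raise ValueError("n_conformations must be >= 1")
        if not 0 < self.s_min < self.s_max:
            raise ValueError("need 0 < s_min < s_max")
        for combo in self.combinations:
            KnotId.parse(combo.knot)  # validates the knot id
            AnnealingTriplet(*combo.triplet)  # validates the triplet


_CONFIG_KEYS = {f.name for f in dataclasses.fields(SweepConfig)}


def load_config(path: str | Path) -> SweepConfig:
    """Load and validate a YAML/JSON sweep configuration.

    A named ``profile`` fills scale parameters first; explicit keys in the
    file override it.  Unknown keys are rejected with a field-level message.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; allowed: {sorted(_CONFIG_KEYS)}")
    values: dict[str, Any] = {}
    profile = raw.get("profile")
    if profile is not None:
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}; available: {sorted(PROFILES)}")
        values.update(PROFILES[profile])
    values.update(raw)
    combos_raw = values.pop("combinations", None)
    if not combos_raw:
        raise ValueError("config must list at least one combination (knot + triplet)")
    combos = []
    for c in combos_raw:
        if not isinstance(c, dict) or "knot" not in c or "triplet" not in c:
            raise ValueError(f"each combination needs 'knot' and 'triplet': {c!r}")
        if isinstance(c["knot"], int):
            raise ValueError(
                f"knot id {c['knot']!r} was parsed as a number; quote it in YAML (e.g. knot: '0_1')"
            )
        extra = set(c) - {"knot", "triplet"}
        if extra:
            raise ValueError(f"unknown combination keys {sorted(extra)} in {c!r}")
        trip = tuple(float(x) for x in c["triplet"])
        if len(trip) != 3:
            raise ValueError(f"triplet must have 3 entries: {c['triplet']!r}")
        combos.append(Combination(knot=str(c["knot"]), triplet=trip))
    return SweepConfig(combinations=combos, **values)


def _fit_payload(fit) -> dict[str, Any]:
    return {
        "slope": fit.slope,
        "stderr": fit.stderr,
        "ci95": list(fit.ci95),
        "bootstrap_se": fit.bootstrap_se,
        "s_min": fit.s_min,
        "s_max": fit.s_max,
        "n_points": fit.n_points,
    }


def analyze_ensemble(
    polygons,
    s_min: int,
    s_max: int,
    diagonal_weight: float,
    n_boot: int,
    boot_seed: int,
):
    """Curves, ensemble average and slope fits for a list of polygons."""
    curves = [contact_curve(p, diagonal_weight) for p in polygons]
    avg = ensemble_average(curves)
    if len(curves) >= 2 and n_boot > 0:
        _, bse_p = bootstrap_slope(curves, "P", s_min, s_max, n_boot=n_boot, seed=boot_seed)
        _, bse_r = bootstrap_slope(curves, "R", s_min, s_max, n_boot=n_boot, seed=boot_seed + 1)
    else:
        bse_p = bse_r = None
    fit_p = fit_loglog_slope(avg, s_min, s_max, "P", bootstrap_se=bse_p)
    fit_r = fit_loglog_slope(avg, s_min, s_max, "R", bootstrap_se=bse_r)
    return curves, avg, fit_p, fit_r


def _write_curve_tsv(avg, path: Path) -> None:
    df = pd.DataFrame({"s": avg.s, "P": avg.P, "R": avg.R, "n_pairs": avg.n_pairs})
    df.to_csv(path, sep="\t", index=False)


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Run every (knot, triplet) combination and tabulate the slope fits.

    Failures of individual combinations are recorded in the table (column
    ``error``) and the sweep continues.  Returns the results table, which is
    also written to ``<out_dir>/sweep_table.tsv`` together with per-run
    artifacts and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    manifest: dict[str, Any] = {
        "package_version": _pkg_version,
        "config": {
            **{k: getattr(config, k) for k in _CONFIG_KEYS - {"combinations"}},
            "combinations": [dataclasses.asdict(c) for c in config.combinations],
        },
        "runs": [],
    }
    confinement = SphericalConfinement(config.radius)
    for idx, combo in enumerate(config.combinations):
        label = combo.label()
        run_dir = out / label
        run_dir.mkdir(exist_ok=True)
        combo_seed = derive_seed(config.seed, idx)
        t0 = time.time()
        entry: dict[str, Any] = {"label": label, "knot": combo.knot, "triplet": list(combo.triplet), "seed": combo_seed}
        try:
            globules = generate_ensemble(
                combo.knot,
                AnnealingTriplet(*combo.triplet),
                confinement,
                config.target_length,
                config.n_conformations,
                base_seed=combo_seed,
                randomize_steps=config.randomize_steps,
            )
            polys = [g.polygon for g in globules]
            write_conformations(
                polys,
                run_dir / "conformations.txt",
                comments=[
                    f"knot={combo.knot} triplet={combo.triplet} radius={config.radius}",
                    f"target_length={config.target_length} seed={combo_seed}",
                ],
            )
            curves, avg, fit_p, fit_r = analyze_ensemble(
                polys,
                config.s_min,
                config.s_max,
                config.diagonal_weight,
                config.bootstrap,
                derive_seed(combo_seed, 0xB0),
            )
            _write_curve_tsv(avg, run_dir / "ensemble_curve.tsv")
            fit_report = {
                "contact": _fit_payload(fit_p),
                "end_to_end": _fit_payload(fit_r),
                "fill_fraction": globules[0].fill_fraction,
                "n_conformations": len(polys),
            }
            with open(run_dir / "fit.json", "w", encoding="utf-8") as fh:
                json.dump(fit_report, fh, indent=2)
            rows.append(
                {
                    "knot": combo.knot,
                    "p_minus2": combo.triplet[0],
                    "p_zero": combo.triplet[1],
                    "p_plus2": combo.triplet[2],
                    "contact_slope": fit_p.slope,
                    "contact_se": fit_p.stderr,
                    "contact_boot_se": fit_p.bootstrap_se,
                    "contact_ci_lo": fit_p.ci95[0],
                    "contact_ci_hi": fit_p.ci95[1],
                    "r_slope": fit_r.slope,
                    "r_se": fit_r.stderr,
                    "r_boot_se": fit_r.bootstrap_se,
                    "n_conformations": len(polys),
                    "error": "",
                }
            )
            entry["status"] = "ok"
        except Exception as exc:  # record and continue with the next combo
            rows.append(
                {
                    "knot": combo.knot,
                    "p_minus2": combo.triplet[0],
                    "p_zero": combo.triplet[1],
                    "p_plus2": combo.triplet[2],
                    "contact_slope": np.nan,
                    "contact_se": np.nan,
                    "contact_boot_se": np.nan,
                    "contact_ci_lo": np.nan,
                    "contact_ci_hi": np.nan,
                    "r_slope": np.nan,
                    "r_se": np.nan,
                    "r_boot_se": np.nan,
                    "n_conformations": 0,
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
            entry["status"] = f"error: {exc}"
        entry["runtime_s"] = round(time.time() - t0, 2)
        manifest["runs"].append(entry)
    table = pd.DataFrame(rows)
    table.to_csv(out / "sweep_table.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return table
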