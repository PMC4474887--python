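"""Figure-style outputs and run provenance.

Every figure written here has a CSV twin holding exactly the plotted
numbers, so no quantity exists only as pixels.  Plot styling comes from a
style mapping (rcParams), never from code constants, so panel comparison is
a configuration concern.  :func:`write_run_record` captures the config hash,
parameter set, typo-policy flags, software version, per-stage timings and an
inventory of output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # headless rendering; never require a display
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .bifurcation_analysis import CollapseCurve, DoseScan, PhaseDiagram
from .dynamics_features import find_maxima
from .model_core import ParameterSet, config_from_parameters

__all__ = [
    "MissingResultsError",
    "RunRecord",
    "config_hash",
    "render_panels",
    "write_run_record",
]

PANEL_DOSES = (0.0, 0.1, 1.0, 5.0, 10.0)


class MissingResultsError(RuntimeError):
    """A panel was requested before its upstream results were computed."""


def config_hash(cfg: Mapping) -> str:
    """Stable hash of a flat config mapping (changes iff the config does)."""
    canon = json.dumps(dict(cfg), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _require_doses(scan: DoseScan, doses: Sequence[float], what: str) -> None:
    missing = [d for d in doses if float(d) not in scan.series]
    if missing:
        raise MissingResultsError(
            f"{what} needs trajectories at doses {missing}; run "
            f"`p53cycle scan` (or run_dose_scan) including those doses first"
        )


def _csv_twin(df: pd.DataFrame, png_path: Path) -> Path:
    csv_path = png_path.with_suffix(".csv")
    df.to_csv(csv_path, index=False)
    return csv_path


def _apply_style(style: Mapping | None):
    rc = {"figure.dpi": 110, "lines.linewidth": 0.9, "font.size": 8}
    if style:
        rc.update(style)
    return plt.rc_context(rc)


def render_panels(
    results: Mapping,
    which: str,
    outdir: str | Path,
    style: Mapping | None = None,
) -> list[Path]:
    """Render one figure family (fig2 .. fig6) from computed results.

    ``results`` is a mapping with the upstream objects each family needs:
    ``scan`` (DoseScan) for fig2/fig4/fig5/fig6, plus ``phase``
    (PhaseDiagram) and ``collapse`` (CollapseCurve) for fig3.  Returns the
    list of files written (every PNG is accompanied by a CSV twin).
    Missing upstream results raise :class:`MissingResultsError` naming the
    command to run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if which not in {"fig2", "fig3", "fig4", "fig5", "fig6"}:
        raise ValueError(f"unknown panel family {which!r}")
    if which in {"fig2", "fig4", "fig5", "fig6"} and "scan" not in results:
        raise MissingResultsError(
            f"{which} needs a dose scan; run `p53cycle scan` first")
    written: list[Path] = []
    with _apply_style(style):
        if which == "fig2":
            written += _fig_timecourses(results["scan"], ("p53", "mdm2"),
                                        outdir / "fig2_p53_mdm2.png")
        elif which == "fig3":
            for key, cmd in (("phase", "p53cycle phase"),
                             ("collapse", "p53cycle collapse-fit")):
                if key not in results:
                    raise MissingResultsError(
                        f"fig3 needs {key!r} results; run `{cmd}` first")
            written += _fig_phase(results["phase"], results["collapse"],
                                  outdir / "fig3_phase_diagram.png")
        elif which in {"fig4", "fig5"}:
            species = "cyclin" if which == "fig4" else "mpf"
            written += _fig_bifurcation(results["scan"], species,
                                        outdir / f"{which}_{species}.png")
        elif which == "fig6":
            written += _fig_maxima_vs_dose(results["scan"],
                                           outdir / "fig6_maxima_vs_dose.png")
    return written


def _fig_timecourses(scan: DoseScan, species: Sequence[str],
                     path: Path) -> list[Path]:
    doses = [d for d in PANEL_DOSES if float(d) in scan.series]
    _require_doses(scan, doses or PANEL_DOSES, "fig2")
    fig, axes = plt.subplots(len(doses), len(species), sharex=True,
                             figsize=(3.2 * len(species), 1.4 * len(doses)),
                             squeeze=False)
    frames = []
    for row, dose in enumerate(doses):
        for col, name in enumerate(species):
            t, v = scan.get(dose, name)
            axes[row][col].plot(t, v)
            axes[row][col].set_ylabel(f"{name}\nIR={dose:g}")
            frames.append(pd.DataFrame(
                {"ir_gy": dose, "species": name, "time_h": t, "value": v}))
    for col in range(len(species)):
        axes[-1][col].set_xlabel("time (h)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return [path, _csv_twin(pd.concat(frames, ignore_index=True), path)]


def _fig_phase(phase: PhaseDiagram, curve: CollapseCurve,
               path: Path) -> list[Path]:
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(7, 2.8))
    df = phase.to_frame()
    ax1.scatter(df["ir_gy"], df["maximum"], s=2)
    ax1.set_xlabel("IR (Gy)")
    ax1.set_ylabel(f"late-time {phase.species} maxima")
    if phase.boundary_gy is not None:
        ax1.axvline(phase.boundary_gy, ls="--")
    m = ~curve.censored
    ax2.plot(curve.doses[m], curve.delta_t_h[m], "o-", ms=2)
    if curve.censored.any():
        ax2.plot(curve.doses[~m], curve.delta_t_h[~m], "x", ms=3)
    ax2.set_xlabel("IR (Gy)")
    ax2.set_ylabel(r"$\Delta t$ (h)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    twin = pd.merge(df, curve.to_frame(), on="ir_gy", how="outer")
    return [path, _csv_twin(twin, path)]


def _fig_bifurcation(scan: DoseScan, species: str, path: Path) -> list[Path]:
    doses = [d for d in PANEL_DOSES if float(d) in scan.series]
    _require_doses(scan, doses or PANEL_DOSES, f"bifurcation ({species})")
    fig, axes = plt.subplots(len(doses), 2, sharex=True,
                             figsize=(6.4, 1.4 * len(doses)), squeeze=False)
    frames = []
    for row, dose in enumerate(doses):
        t, v = scan.get(dose, species)
        axes[row][0].plot(t, v)
        axes[row][0].set_ylabel(f"{species}\nIR={dose:g}")
        maxima = find_maxima((t, v), species=species)
        axes[row][1].scatter(maxima.times_h, maxima.values, s=2)
        frames.append(pd.DataFrame({"ir_gy": dose,
                                    "time_h": maxima.times_h,
                                    "maximum": maxima.values}))
    axes[-1][0].set_xlabel("time (h)")
    axes[-1][1].set_xlabel("time (h)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return [path, _csv_twin(pd.concat(frames, ignore_index=True), path)]


def _fig_maxima_vs_dose(scan: DoseScan, path: Path) -> list[Path]:
    from .bifurcation_analysis import maxima_vs_dose

    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(5, 4.2))
    frames = []
    for ax, species in zip(axes, ("mpf", "cyclin")):
        df = maxima_vs_dose(scan, species=species)
        ax.scatter(df["ir_gy"], df["maximum"], s=2)
        ax.set_ylabel(f"{species} maxima")
        df.insert(0, "species", species)
        frames.append(df)
    axes[-1].set_xlabel("IR (Gy)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return [path, _csv_twin(pd.concat(frames, ignore_index=True), path)]


@dataclass
class RunRecord:
    """Provenance of one analysis run."""

    config_hash: str
    config: dict
    version: str
    timings_s: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    seed: int | None = None
    created_unix: float = field(default_factory=time.time)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


def write_run_record(
    params_or_config: ParameterSet | Mapping,
    outdir: str | Path,
    outputs: Sequence[str | Path] = (),
    timings_s: Mapping[str, float] | None = None,
    seed: int | None = None,
    filename: str = "run_record.json",
) -> RunRecord:
    """Write a JSON provenance record next to the outputs it describes.

    Re-running with the same config reproduces the same hash; the record
    lists exactly the files passed as ``outputs`` (paths relative to
    ``outdir`` where possible).
    """
    cfg = (config_from_parameters(params_or_config)
           if isinstance(params_or_config, ParameterSet)
           else dict(params_or_config))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rel_outputs = []
    for out in outputs:
        p = Path(out)
        try:
            rel_outputs.append(str(p.relative_to(outdir)))
        except ValueError:
            rel_outputs.append(str(p))
    record = RunRecord(
        config_hash=config_hash(cfg),
        config=cfg,
        version=__version__,
        timings_s=dict(timings_s or {}),
        outputs=sorted(rel_outputs),
        seed=seed,
    )
    (outdir / filename).write_text(record.to_json())
    return record
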