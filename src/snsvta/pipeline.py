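"""Config-driven end-to-end runs and model comparisons.

``run_from_config`` executes a validated run description (YAML): build
anatomy, implant hardware, solve each stimulation setting, run the
40-axon activation criterion, and export a summary CSV mirroring the
per-setting activation table plus a manifest with every resolved
default.  ``run_activation_sweep`` is the 12-setting sweep over both
lead models; ``compare_models`` reports the contact-configuration
contrasts between and within lead models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anatomy import PelvisParams, TissueModel, make_homogeneous, make_synthetic_pelvis, save_tissue
from .field import StimConfig, Waveform, field_to_nifti, field_to_vtk
from .geometry import DEFAULT_TIP_OFFSET_MM, IpgSpec, Placement, make_electrode
from .vta import ActivationSummary, AxonGridSpec, compute_vta_map, run_configuration

__all__ = [
    "ConfigError", "RunConfig", "run_from_config",
    "run_activation_sweep", "table1_stim_set", "compare_models",
    "default_placement", "default_ipg",
]

#: three pulses at 14 Hz (the fourth onset would fall at 214.3 ms)
THREE_PULSE_DURATION_MS = 214.0

DEFAULT_IPG_CENTER_MM = (120.0, 75.0, 70.0)
DEFAULT_TIP_X_MM = 50.0
DEFAULT_FORAMEN_INDEX = 1


class ConfigError(ValueError):
    pass


def default_placement(tissue: TissueModel, foramen_index: int = DEFAULT_FORAMEN_INDEX,
                      tip_x_mm: float = DEFAULT_TIP_X_MM) -> Placement:
    """Thread the lead through a foramen channel along +x.

    Uses the foramen centres recorded by the synthetic-anatomy generator;
    for volumes without them (e.g. homogeneous) the lead runs along the
    volume centre line.
    """
    centers = tissue.meta.get("foramen_centers_mm")
    if centers:
        fy, fz = centers[foramen_index]
    else:
        ext = tissue.extent
        fy, fz = ext[1] / 2.0, ext[2] / 2.0
    return Placement((tip_x_mm, float(fy), float(fz)), (1.0, 0.0, 0.0))


def default_ipg() -> IpgSpec:
    return IpgSpec(DEFAULT_IPG_CENTER_MM)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated end-to-end run description with all defaults resolved."""

    seed: int
    output_dir: Path
    anatomy_kind: str
    anatomy_params: PelvisParams
    electrode_model: int
    placement: Placement | None            # None -> default from anatomy
    foramen_index: int
    tip_offset_mm: float
    ipg: IpgSpec
    stims: list[StimConfig]
    axon_grid: AxonGridSpec
    solver_tol: float
    dt_ms: float
    export_fields: bool
    export_vta_maps: bool

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        errors: list[str] = []

        def need(path, d, key, default=None, required=False):
            if key in d:
                return d[key]
            if required:
                errors.append(f"missing required key: {path}{key}")
            return default

        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        seed = int(need("", raw, "seed", 0))
        output_dir = Path(need("", raw, "output_dir", "results/run"))

        anat = raw.get("anatomy", {})
        kind = need("anatomy.", anat, "kind", "synthetic_pelvis")
        if kind not in ("synthetic_pelvis", "homogeneous"):
            errors.append(f"anatomy.kind must be synthetic_pelvis or homogeneous, got {kind!r}")
        pkw = {k: v for k, v in anat.items() if k != "kind"}
        try:
            pparams = PelvisParams(**{k: tuple(v) if isinstance(v, list) else v
                                      for k, v in pkw.items()})
        except TypeError as e:
            errors.append(f"anatomy: {e}")
            pparams = PelvisParams()

        elec = raw.get("electrode", {})
        model = need("electrode.", elec, "model", required=True)
        try:
            if model is not None:
                make_electrode(int(model))
        except ValueError as e:
            errors.append(str(e))
        tip_offset = float(need("electrode.", elec, "tip_offset_mm", DEFAULT_TIP_OFFSET_MM))

        plc = raw.get("placement", {})
        placement = None
        if "tip_position_mm" in plc:
            try:
                placement = Placement(tuple(plc["tip_position_mm"]),
                                      tuple(plc.get("axis_direction", (1.0, 0.0, 0.0))))
            except ValueError as e:
                errors.append(f"placement: {e}")
        foramen_index = int(plc.get("foramen_index", DEFAULT_FORAMEN_INDEX))

        ipg_raw = raw.get("ipg", {})
        ipg = IpgSpec(tuple(ipg_raw.get("center_mm", DEFAULT_IPG_CENTER_MM)),
                      tuple(ipg_raw.get("dimensions_mm", (55.0, 60.0, 10.0))))

        stims = []
        stim_raw = raw.get("stimulation", [])
        if not stim_raw:
            errors.append("stimulation: at least one setting is required")
        for i, s in enumerate(stim_raw):
            try:
                wf = Waveform(float(s.get("frequency_hz", 14.0)),
                              float(s.get("pulse_width_ms", 0.21)),
                              float(s.get("duration_ms", THREE_PULSE_DURATION_MS)))
                anode = s.get("anode", "ipg")
                stims.append(StimConfig(s.get("mode", "monopolar"),
                                        int(s["cathode"]),
                                        anode if anode == "ipg" else int(anode),
                                        float(s.get("amplitude_v", 1.0)), wf))
            except (KeyError, ValueError) as e:
                errors.append(f"stimulation[{i}]: {e}")

        ax = raw.get("axon_grid", {})
        grid = AxonGridSpec(int(ax.get("axons_per_group", 10)),
                            float(ax.get("spacing_mm", 0.5)),
                            float(ax.get("clearance_mm", 1.0)),
                            float(ax.get("length_mm", 100.0)))
        solver_tol = float(raw.get("solver", {}).get("tol", 1e-8))
        dt_ms = float(raw.get("sim", {}).get("dt_ms", 0.005))
        exp = raw.get("export", {})

        if errors:
            raise ConfigError("invalid run config:\n  " + "\n  ".join(errors))
        return cls(seed, output_dir, kind, pparams, int(model), placement,
                   foramen_index, tip_offset, ipg, stims, grid, solver_tol, dt_ms,
                   bool(exp.get("fields", False)), bool(exp.get("vta_maps", False)))

    def resolved(self) -> dict:
        """Plain-dict echo of every resolved setting (for the manifest)."""
        return {
            "package_version": __version__,
            "seed": self.seed,
            "anatomy": {"kind": self.anatomy_kind,
                        **dataclasses.asdict(self.anatomy_params)},
            "electrode": {"model": self.electrode_model,
                          "tip_offset_mm": self.tip_offset_mm},
            "placement": None if self.placement is None else {
                "tip_position_mm": list(self.placement.tip_position),
                "axis_direction": list(self.placement.axis_direction)},
            "foramen_index": self.foramen_index,
            "ipg": {"center_mm": list(self.ipg.center),
                    "dimensions_mm": list(self.ipg.dimensions)},
            "stimulation": [
                {"mode": s.mode, "cathode": s.cathode_contact, "anode": s.anode,
                 "amplitude_v": s.amplitude,
                 "frequency_hz": s.waveform.frequency_hz,
                 "pulse_width_ms": s.waveform.pulse_width_ms,
                 "duration_ms": s.waveform.duration_ms} for s in self.stims],
            "axon_grid": dataclasses.asdict(self.axon_grid),
            "solver_tol": self.solver_tol,
            "dt_ms": self.dt_ms,
        }


def _build_anatomy(cfg: RunConfig) -> TissueModel:
    if cfg.anatomy_kind == "homogeneous":
        return make_homogeneous(cfg.anatomy_params)
    return make_synthetic_pelvis(cfg.anatomy_params, seed=cfg.seed)


def run_from_config(config: str | Path | dict) -> Path:
    """Execute a full run; returns the output directory.

    Writes ``summary.csv`` (one row per stimulation setting),
    ``manifest.yaml`` (resolved config, seed, solver diagnostics, and any
    stage errors) and, when requested, per-setting potential fields
    (NIfTI + VTK) and VTA rasters (PNG + CSV).
    """
    if isinstance(config, (str, Path)):
        raw = yaml.safe_load(Path(config).read_text())
    else:
        raw = config
    cfg = RunConfig.from_dict(raw)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    tissue = _build_anatomy(cfg)
    placement = cfg.placement or default_placement(tissue, cfg.foramen_index)
    electrode = make_electrode(cfg.electrode_model)

    rows = []
    diag = []
    errors = []
    cache: dict = {}
    for stim in cfg.stims:
        try:
            summary = run_configuration(tissue, electrode, placement, cfg.ipg, stim,
                                        cfg.axon_grid, cfg.tip_offset_mm, cfg.solver_tol,
                                        cfg.dt_ms, _field_cache=cache)
        except Exception as e:  # noqa: BLE001 - stage failures recorded, run continues
            errors.append({"stim": stim.label, "error": str(e)})
            continue
        rows.append(summary.to_row())
        diag.append({"stim": stim.label, **summary.meta["solver"]})
        if cfg.export_fields:
            fieldv = cache[(electrode.model_id, StimConfig(stim.mode, stim.cathode_contact,
                                                           stim.anode, 1.0, stim.waveform).label)]
            field_to_nifti(fieldv, out / f"field_{electrode.model_id}_{stim.label}.nii")
            field_to_vtk(fieldv, out / f"field_{electrode.model_id}_{stim.label}.vtk")
        if cfg.export_vta_maps:
            vmap = compute_vta_map(tissue, electrode, placement, cfg.ipg, stim,
                                   axon_spec=cfg.axon_grid, tip_offset=cfg.tip_offset_mm,
                                   solver_tol=cfg.solver_tol, dt=cfg.dt_ms)
            save_vta_map(vmap, out / f"vta_{electrode.model_id}_{stim.label}")

    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
    manifest = {"config": cfg.resolved(), "solver_diagnostics": diag,
                "placement_used": {"tip_position_mm": list(placement.tip_position),
                                   "axis_direction": list(placement.axis_direction)},
                "errors": errors, "status": "error" if errors else "ok"}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    save_tissue(tissue, out / "tissue_labels.nii") if cfg.export_fields else None
    return out


def save_vta_map(vmap, stem: str | Path) -> None:
    """PNG (white = 1:1 firing, black = not) plus a numeric CSV grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.where(vmap.interior_mask, 0.5, vmap.activated.astype(float))
    plt.imsave(str(Path(f"{stem}.png")), img.T[::-1], cmap="gray", vmin=0, vmax=1)
    df = pd.DataFrame(vmap.activated.astype(int),
                      index=pd.Index(vmap.offsets_y_mm, name="offset_y_mm"),
                      columns=pd.Index(vmap.offsets_z_mm, name="offset_z_mm"))
    df.to_csv(Path(f"{stem}.csv"))


# ---------------------------------------------------------------------------
# activation sweep (percent-activation table over both electrodes)
# ---------------------------------------------------------------------------

def table1_stim_set(amplitude_v: float = 1.0,
                    duration_ms: float = THREE_PULSE_DURATION_MS) -> list[StimConfig]:
    """The 12-setting sweep: 4 monopolar cathodes + 2 bipolar pairings per model."""
    wf = Waveform(duration_ms=duration_ms)
    return ([StimConfig("monopolar", c, "ipg", amplitude_v, wf) for c in range(4)]
            + [StimConfig("bipolar", 0, 1, amplitude_v, wf),
               StimConfig("bipolar", 1, 0, amplitude_v, wf)])


def run_activation_sweep(tissue: TissueModel, placement: Placement | None = None,
                         ipg: IpgSpec | None = None, models=(3093, 3889),
                         stims: list[StimConfig] | None = None,
                         grid: AxonGridSpec | None = None,
                         tip_offset: float = DEFAULT_TIP_OFFSET_MM,
                         solver_tol: float = 1e-8, dt: float = 0.005,
                         ) -> tuple[pd.DataFrame, list[ActivationSummary]]:
    """Percent activation for every (model, setting) pair on one tissue volume."""
    placement = placement or default_placement(tissue)
    ipg = ipg or default_ipg()
    stims = stims or table1_stim_set()
    cache: dict = {}
    rows, summaries = [], []
    for model in models:
        electrode = make_electrode(model)
        for stim in stims:
            summary = run_configuration(tissue, electrode, placement, ipg, stim,
                                        grid, tip_offset, solver_tol, dt,
                                        _field_cache=cache)
            rows.append(summary.to_row())
            summaries.append(summary)
    return pd.DataFrame(rows), summaries


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------

def _canon_model(m) -> int:
    m = int(m)
    return 3889 if m == 3389 else m


def compare_models(summary: pd.DataFrame | str | Path) -> dict:
    """Contrasts of an activation-percentage table.

    Returns per-configuration between-model differences (3093 - 3889),
    within-model contrasts (long-contact-1 cathode vs contact-0 cathode,
    monopolar vs bipolar), and a list of configurations missing from the
    input (reported, not fatal).
    """
    if not isinstance(summary, pd.DataFrame):
        summary = pd.read_csv(summary)
    df = summary.copy()
    df["electrode_model"] = df["electrode_model"].map(_canon_model)
    df["configuration"] = df["configuration"].str.lower()

    def pct(model, conf, contact):
        sel = df[(df.electrode_model == model) & (df.configuration == conf)
                 & (df.activated_contact == contact)]
        if sel.empty:
            return None
        return float(sel["percent_activation"].iloc[0])

    expected = [(m, conf, c) for m in (3093, 3889)
                for conf, cs in (("monopolar", range(4)), ("bipolar", range(2)))
                for c in cs]
    missing = [f"{m} {conf} contact {c}" for m, conf, c in expected
               if pct(m, conf, c) is None]

    between = []
    for conf, cs in (("monopolar", range(4)), ("bipolar", range(2))):
        for c in cs:
            a, b = pct(3093, conf, c), pct(3889, conf, c)
            if a is not None and b is not None:
                between.append({"configuration": conf, "activated_contact": c,
                                "pct_3093": a, "pct_3889": b, "difference": a - b})

    within = {}
    for m in (3093, 3889):
        w = {}
        mono0, mono1 = pct(m, "monopolar", 0), pct(m, "monopolar", 1)
        bip0, bip1 = pct(m, "bipolar", 0), pct(m, "bipolar", 1)
        if mono0 is not None and mono1 is not None:
            w["monopolar_c1_minus_c0"] = mono1 - mono0
        if bip0 is not None and bip1 is not None:
            w["bipolar_c1_minus_c0"] = bip1 - bip0
        if mono0 is not None and bip0 is not None:
            w["bipolar_minus_monopolar_c0"] = bip0 - mono0
        within[m] = w

    return {"between_models": pd.DataFrame(between), "within_model": within,
            "missing": missing}
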