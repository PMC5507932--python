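"""Per-cell orchestration: image set → CellRecord → study table → fits.

The study runs in two passes.  Pass one processes every image set into a
per-cell record (nucleus geometry, chromatin scores, cytoskeletal metrics);
pass two computes the population-level quantities that need the full table
— the median integrated DAPI intensity that anchors the undeformed-radius
estimate, and the per-protein median that normalizes CSK amounts — and then
fills in the mechanics columns.  Partial failures flag the missing fields
on the record instead of aborting the study; skipped cells are logged with
a reason.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin as chrom
from . import cytoskeleton as csk
from . import mechanics as mech
from . import morphology as morph
from . import stats
from .core import CalibratedImage, DomainError, NucmechError, read_tiff

log = logging.getLogger("nucmech")

PROTEINS = ("actin", "myosin", "tubulin", "vimentin")


@dataclasses.dataclass
class PipelineConfig:
    """Physical constants and thresholds the imaging setup leaves implicit."""

    pixel_size: float = 0.32        # µm/px
    calibration_k: float = 1.0      # fluorescence units per µm thickness
    depth_of_focus: float = 3.0     # µm
    r_bar: float = 12.9             # µm, mean undeformed nuclear radius
    bandpass_low: float = 0.75      # µm
    bandpass_high: float = 2.5      # µm
    min_nucleus_area: float = 20.0  # µm²
    min_cell_area: float = 200.0    # µm²
    cell_threshold_k: float = 2.0
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("pixel_size", "calibration_k", "depth_of_focus", "r_bar",
                     "bandpass_low", "bandpass_high", "min_nucleus_area",
                     "min_cell_area"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def process_cell(images: dict[str, CalibratedImage], config: PipelineConfig,
                 cell_id: str = "cell", group: str = "control") -> dict:
    """One image set (DAPI plus any protein channels) → one CellRecord row.

    Mechanics columns need population medians and are filled by
    ``run_study``; stand-alone callers can pass the record to
    ``mechanics.compute_mechanics`` themselves.
    """
    if "dapi" not in images:
        raise DomainError("DAPI channel is required")
    record: dict = {"cell_id": cell_id, "group": group}
    flags: list[str] = []

    try:
        dapi = images["dapi"]
        nucleus = morph.segment_nucleus(dapi, config.min_nucleus_area)
        profile = morph.radial_profile(dapi, nucleus)
        height = morph.fit_height(profile, config.calibration_k,
                                  config.depth_of_focus)
        geom = morph.measure_geometry(dapi, nucleus, height)
        record.update(a=geom.a, b=geom.b, c=geom.c, height=geom.height,
                      theta_nuc=geom.theta_nuc, i_total=geom.i_total,
                      aspect_ratio_xy=geom.aspect_ratio_xy,
                      nucleus_area=nucleus.projected_area)
        if geom.degenerate_orientation:
            flags.append("degenerate_nucleus_orientation")
        tmap = chrom.thickness_map_from_geometry(geom, dapi.shape,
                                                 dapi.pixel_size)
        metrics = chrom.chromatin_condensation(
            dapi, nucleus, tmap, config.depth_of_focus,
            chrom.BandpassSpec(config.bandpass_low, config.bandpass_high))
        record.update(cc=metrics.cc, cc_peripheral=metrics.cc_peripheral,
                      thick_region_area=metrics.thick_region_area)
        flags.extend(metrics.flags)
    except NucmechError as exc:
        log.warning("cell %s: nuclear analysis failed: %s", cell_id, exc)
        flags.append(f"nucleus_failed:{type(exc).__name__}")

    csa_values = []
    for protein in PROTEINS:
        if protein not in images:
            continue
        try:
            img = images[protein]
            mask, csa = csk.segment_cell(img, config.cell_threshold_k,
                                         config.min_cell_area)
            maps = csk.segment_fibres(img, mask)
            metrics = csk.fibre_descriptors(maps, csa)
            record[f"{protein}_amount_raw"] = metrics.csk_amount_raw
            record[f"{protein}_anisotropy"] = metrics.anisotropy
            record[f"{protein}_theta_fib"] = metrics.theta_fib
            csa_values.append(csa)
            flags.extend(f"{protein}:{f}" for f in metrics.flags)
        except NucmechError as exc:
            log.warning("cell %s/%s: cytoskeleton failed: %s",
                        cell_id, protein, exc)
            flags.append(f"{protein}_failed:{type(exc).__name__}")
    if csa_values:
        record["csa"] = float(np.mean(csa_values))
    else:
        flags.append("no_csk_channel")
    record["flags"] = ";".join(flags)
    return record


def _load_manifest(path: str | Path) -> list[dict]:
    data = yaml.safe_load(Path(path).read_text())
    cells = data.get("cells") if isinstance(data, dict) else data
    if not cells:
        raise DomainError("empty manifest")
    return cells


def run_study(manifest: str | Path | list[dict], config: PipelineConfig
              ) -> pd.DataFrame:
    """Process every image set listed in a manifest and finish the
    population-level columns (mechanics, normalized CSK amounts).

    Manifest entries: ``{id, group, dapi: path, channels: {protein: path}}``.
    Deterministic given the config; CSK normalization is a median over the
    full population, hence order-invariant.
    """
    entries = (_load_manifest(manifest)
               if isinstance(manifest, (str, Path)) else manifest)
    if not entries:
        raise DomainError("empty manifest")
    records = []
    for entry in entries:
        cell_id = str(entry.get("id", len(records)))
        try:
            images = {"dapi": read_tiff(entry["dapi"], config.pixel_size)}
            for protein, p in (entry.get("channels") or {}).items():
                images[protein] = read_tiff(p, config.pixel_size)
        except (OSError, ValueError, KeyError, NucmechError) as exc:
            log.warning("cell %s skipped: unreadable input (%s)", cell_id, exc)
            continue
        records.append(process_cell(images, config, cell_id,
                                    str(entry.get("group", "control"))))
    if not records:
        raise DomainError("no processable cells in manifest")
    table = pd.DataFrame(records)
    return finalize_population(table, config)


def finalize_population(table: pd.DataFrame, config: PipelineConfig
                        ) -> pd.DataFrame:
    """Second pass: mechanics from the population I_T median, plus
    median-normalized CSK amounts per protein."""
    table = table.copy()
    if "i_total" in table.columns and table["i_total"].notna().any():
        params = mech.MechanicsParams(
            r_bar=config.r_bar,
            i_total_median=float(table["i_total"].median()))
        cols = {k: [] for k in ("r", "v0", "volume", "delta_v_over_v",
                                "delta_l_over_l", "nu", "e_mod")}
        for _, row in table.iterrows():
            if not (np.isfinite(row.get("i_total", np.nan))
                    and np.isfinite(row.get("height", np.nan))):
                for v in cols.values():
                    v.append(np.nan)
                continue
            geom = morph.NucleusGeometry(
                a=row["a"], b=row["b"], c=row["c"], height=row["height"],
                theta_nuc=row["theta_nuc"], i_total=row["i_total"],
                aspect_ratio_xy=row["aspect_ratio_xy"], centroid_rc=(0, 0))
            m = mech.compute_mechanics(geom, row.get("csa", None)
                                       if np.isfinite(row.get("csa", np.nan))
                                       else None, params)
            cols["r"].append(m.r)
            cols["v0"].append(m.v0_undeformed)
            cols["volume"].append(m.v)
            cols["delta_v_over_v"].append(m.delta_v_over_v)
            cols["delta_l_over_l"].append(m.delta_l_over_l)
            cols["nu"].append(m.nu if m.nu is not None else np.nan)
            cols["e_mod"].append(m.e_mod if m.e_mod is not None else np.nan)
        for k, v in cols.items():
            table[k] = v
    for protein in PROTEINS:
        raw = f"{protein}_amount_raw"
        if raw in table.columns and table[raw].notna().sum() >= 2:
            med = table[raw].median()
            if med > 0:
                table[protein] = table[raw] / med
    return table


def fit_study(table: pd.DataFrame, out_dir: str | Path | None = None) -> dict:
    """Run every applicable population fit on a finished study table.

    Returns (and optionally writes, as JSON plus binned CSVs) the rational
    height law, per-protein power laws, the four global fits, the CC/volume
    slope, ANCOVA across groups when more than one group is present, and
    orientation statistics when fibre orientations are available.
    """
    report: dict = {}
    proteins = [p for p in PROTEINS if p in table.columns]

    def _try(name, fn):
        try:
            report[name] = fn()
        except (NucmechError, KeyError) as exc:
            log.warning("fit %s skipped: %s", name, exc)

    if {"csa", "height"}.issubset(table.columns):
        _try("rational_height",
             lambda: dataclasses.asdict(stats.fit_rational_height(table)))
    for p in proteins:
        _try(f"power_law_{p}",
             lambda p=p: dataclasses.asdict(stats.fit_power_law(table, "csa", p)))
    for resp in ("volume", "nu", "e_mod", "cc"):
        if resp in table.columns and len(proteins) >= 1:
            _try(f"global_fit_{resp}",
                 lambda r=resp: dataclasses.asdict(
                     stats.global_fit(table.dropna(subset=[r] + proteins),
                                      r, tuple(proteins))))
    if {"cc", "volume"}.issubset(table.columns):
        _try("cc_volume_slope",
             lambda: dataclasses.asdict(
                 stats.cc_volume_slope(table.dropna(subset=["cc", "volume"]))))
    if "group" in table.columns and table["group"].nunique() > 1:
        for resp in ("volume", "nu", "e_mod", "cc"):
            if resp in table.columns:
                _try(f"ancova_{resp}",
                     lambda r=resp: dataclasses.asdict(
                         stats.ancova_shared_exponent(
                             table.dropna(subset=[r, "csa"]), r)))
    for p in proteins:
        tf = f"{p}_theta_fib"
        if tf in table.columns and "theta_nuc" in table.columns:
            sub = table.dropna(subset=[tf, "theta_nuc"])
            if len(sub):
                from .core import axial_difference
                diffs = axial_difference(sub["theta_nuc"], sub[tf])
                _try(f"orientation_{p}",
                     lambda d=diffs: dataclasses.asdict(
                         stats.axial_circular_stats(d)))
        aniso = f"{p}_anisotropy"
        if aniso in table.columns and "aspect_ratio_xy" in table.columns:
            sub = table.dropna(subset=[aniso, "aspect_ratio_xy"])
            if len(sub) >= 10:
                _try(f"anisotropy_aspect_{p}",
                     lambda s=sub, a=aniso: dataclasses.asdict(
                         stats.anisotropy_aspect_slope(s, a)))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "fits.json").write_text(
            json.dumps(report, indent=1, default=_json_default))
        if {"csa", "height"}.issubset(table.columns) and len(table) >= 100:
            stats.binned_summary(table, "csa").to_csv(
                out_dir / "binned_by_csa.csv", index=False)
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
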