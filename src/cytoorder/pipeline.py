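"""End-to-end orchestration: manifest -> masks -> correlograms -> order
metrics -> crosstalk -> statistics.

The entry point is :func:`run_analysis`, which consumes a CSV manifest
(columns ``path, pixel_size_nm, channel, cell_id, condition``) and an
:class:`AnalysisConfig`, and returns per-cell and per-condition tables plus
averaged curves.  Failures on individual cells are logged and skipped, never
silently dropped: processed + skipped always reconciles with the manifest
row count.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cytoorder import crosstalk as xt
from cytoorder import order_analysis as oa
from cytoorder.correlation import autocorrelate, normalize_origin
from cytoorder.imaging_io import read_micrograph, resample_to_common_grid
from cytoorder.segmentation import segment_micrograph
from cytoorder.stats import hedges_g, ks_two_sample

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["path", "pixel_size_nm", "channel", "cell_id", "condition"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable parameters of the pipeline, with the standard defaults."""

    target_pixel_size_nm: float = 112.0
    niblack_radius_px: float = 7.0
    r_inner_px: float = 9.0
    r_outer_px: float = 21.0
    max_lag_px: int = 40
    peak_window_px: int = 9
    bg_ring_px: tuple[int, int] = (27, 36)
    normalization: str = "rectangle"  # crosstalk background normalization
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "bg_ring_px" in raw:
            raw["bg_ring_px"] = tuple(raw["bg_ring_px"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["bg_ring_px"] = list(d["bg_ring_px"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class CellResult:
    cell_id: str
    channel: str
    condition: str
    coverage: float
    preferred_direction_deg: float
    rof: oa.RadialOrientationFunction
    rof_at_90: float
    intrinsic_rof: oa.RadialOrientationFunction
    intrinsic_rof_at_90: float
    correlogram: object  # origin-normalized Correlogram
    combined_mask: object
    cell_mask: object = None
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)
    full_shape: tuple[int, int] = (0, 0)


@dataclass
class AnalysisResult:
    per_cell: pd.DataFrame
    condition_averages: dict  # (condition, channel) -> dict of PopulationAverage
    comparisons: pd.DataFrame
    crosstalk_table: pd.DataFrame
    n_processed: int
    n_skipped: int
    skipped: list


def analyze_micrograph(img, config: AnalysisConfig = AnalysisConfig()) -> CellResult:
    """Run the single-cell analysis chain on one (already loaded) micrograph."""
    img = resample_to_common_grid(img, config.target_pixel_size_nm)
    seg = segment_micrograph(img, config.niblack_radius_px)
    max_lag = min(config.max_lag_px, min(seg.combined.shape) - 1)
    if max_lag < config.r_outer_px:
        raise ValueError(
            f"cell too small: analysis region {seg.combined.shape} supports "
            f"max lag {max_lag} < outer annulus radius {config.r_outer_px}"
        )
    corr = normalize_origin(autocorrelate(seg.combined, max_lag))
    rof = oa.radial_orientation(corr, config.r_inner_px, config.r_outer_px)
    pd_deg = oa.preferred_direction(rof)
    aligned = oa.rotate_correlogram(corr, 90.0 - pd_deg)
    irof = oa.radial_orientation(aligned, config.r_inner_px, config.r_outer_px)
    return CellResult(
        cell_id=img.cell_id,
        channel=img.channel,
        condition=img.condition,
        coverage=seg.combined.coverage,
        preferred_direction_deg=pd_deg,
        rof=rof,
        rof_at_90=rof.at_angle(90.0),
        intrinsic_rof=irof,
        intrinsic_rof_at_90=irof.at_angle(90.0),
        correlogram=corr,
        combined_mask=seg.combined,
        cell_mask=seg.cell_mask,
        bbox=seg.bbox,
        full_shape=img.shape,
    )


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("manifest is empty")
    return df


def run_analysis(
    manifest, config: AnalysisConfig = AnalysisConfig()
) -> AnalysisResult:
    """Run the full pipeline over a manifest.

    ``manifest`` is a CSV path or an equivalent DataFrame.  Per cell the
    chain is segmentation, auto-correlation, radial orientation function,
    preferred direction and the ROF value at 90 degrees (raw and intrinsic,
    i.e. after aligning the correlogram to 90 degrees).  Per (condition,
    channel) group it computes unaligned and aligned population averages and
    line profiles; where a cell carries two channels, same-cell crosstalk
    and the random-pair null; and pairwise condition comparisons (KS test
    and Hedges' g) of the per-cell ROF values at 90 degrees.
    """
    df = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
    results: list[CellResult] = []
    skipped = []
    for _, row in df.iterrows():
        try:
            img = read_micrograph(
                row["path"],
                float(row["pixel_size_nm"]),
                channel=str(row["channel"]),
                cell_id=str(row["cell_id"]),
                condition=str(row["condition"]),
            )
            results.append(analyze_micrograph(img, config))
        except (ValueError, OSError) as exc:
            logger.warning("cell %s skipped: %s", row["cell_id"], exc)
            skipped.append((str(row["cell_id"]), str(exc)))
    per_cell = pd.DataFrame(
        {
            "cell_id": [r.cell_id for r in results],
            "channel": [r.channel for r in results],
            "condition": [r.condition for r in results],
            "coverage": [r.coverage for r in results],
            "preferred_direction_deg": [r.preferred_direction_deg for r in results],
            "rof_at_90": [r.rof_at_90 for r in results],
            "intrinsic_rof_at_90": [r.intrinsic_rof_at_90 for r in results],
        }
    )
    condition_averages = {}
    for (cond, chan), group in _groups(results):
        rofs = [r.rof for r in group]
        avg_rof = oa.average_population(rofs)
        aligned_avg = oa.average_population([r.correlogram for r in group], align=True)
        irofs = [r.intrinsic_rof for r in group]
        condition_averages[(cond, chan)] = {
            "rof": avg_rof,
            "intrinsic_rof": oa.average_population(irofs),
            "aligned_correlogram": aligned_avg,
            "n": len(group),
        }
    comparisons = _pairwise_comparisons(per_cell)
    crosstalk_table = _crosstalk(results, config)
    result = AnalysisResult(
        per_cell=per_cell,
        condition_averages=condition_averages,
        comparisons=comparisons,
        crosstalk_table=crosstalk_table,
        n_processed=len(results),
        n_skipped=len(skipped),
        skipped=skipped,
    )
    logger.info(
        "run_analysis: %d processed, %d skipped of %d manifest rows",
        len(results),
        len(skipped),
        len(df),
    )
    if config.output_dir:
        _write_outputs(result, config)
    return result


def _groups(results):
    key = lambda r: (r.condition, r.channel)
    for k, g in itertools.groupby(sorted(results, key=key), key=key):
        yield k, list(g)


def _pairwise_comparisons(per_cell: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for chan, sub in per_cell.groupby("channel"):
        conditions = sorted(sub["condition"].unique())
        for ca, cb in itertools.combinations(conditions, 2):
            for col in ("rof_at_90", "intrinsic_rof_at_90"):
                xa = sub.loc[sub["condition"] == ca, col].to_numpy()
                xb = sub.loc[sub["condition"] == cb, col].to_numpy()
                if len(xa) < 2 or len(xb) < 2:
                    continue
                d, p = ks_two_sample(xa, xb)
                try:
                    es = hedges_g(xa, xb)
                    g, b, sp = es.g, es.b, es.sp
                except ValueError:
                    g = b = sp = np.nan
                rows.append(
                    dict(
                        channel=chan,
                        metric=col,
                        condition_a=ca,
                        condition_b=cb,
                        n1=len(xa),
                        n2=len(xb),
                        D=d,
                        p=p,
                        g=g,
                        b=b,
                        sp=sp,
                    )
                )
    return pd.DataFrame(rows)


def _pair_common_frame(ra: CellResult, rb: CellResult):
    """Crop a registered channel pair to the smallest rectangle enclosing
    both masks in the shared acquisition frame."""
    if ra.full_shape != rb.full_shape:
        raise ValueError(
            f"cell {ra.cell_id}: channel frames differ "
            f"({ra.full_shape} vs {rb.full_shape})"
        )
    r0 = min(ra.bbox[0], rb.bbox[0])
    r1 = max(ra.bbox[1], rb.bbox[1])
    c0 = min(ra.bbox[2], rb.bbox[2])
    c1 = max(ra.bbox[3], rb.bbox[3])
    out = []
    support = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    for r in (ra, rb):
        full = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        br0, br1, bc0, bc1 = r.bbox
        window = np.s_[br0 - r0 : br1 - r0, bc0 - c0 : bc1 - c0]
        full[window] = r.combined_mask.values
        support[window] |= r.cell_mask.values
        out.append(dataclasses.replace(r.combined_mask, values=full))
    from scipy import ndimage as _ndi

    support_mask = dataclasses.replace(
        ra.cell_mask, values=_ndi.binary_fill_holes(support)
    )
    return out[0], out[1], support_mask


def _crosstalk(results, config: AnalysisConfig) -> pd.DataFrame:
    rows = []
    by_cond: dict = {}
    for r in results:
        by_cond.setdefault(r.condition, {}).setdefault(r.cell_id, {})[r.channel] = r
    for cond, cells in by_cond.items():
        pair_channels = {}
        for cid, chans in cells.items():
            names = sorted(chans)
            for a, b in itertools.combinations(names, 2):
                try:
                    ma, mb, support = _pair_common_frame(chans[a], chans[b])
                except ValueError as exc:
                    logger.warning("cell %s crosstalk skipped: %s", cid, exc)
                    continue
                pair_channels.setdefault((a, b), []).append((ma, mb, support))
        for (a, b), masks in pair_channels.items():
            if len(masks) < 1:
                continue
            for region in ("full", "inscribed_circle"):
                try:
                    _, peak = xt.same_cell_crosstalk(
                        masks,
                        region=region,
                        max_lag=config.max_lag_px,
                        peak_window_px=config.peak_window_px,
                        bg_ring_px=config.bg_ring_px,
                        normalization=config.normalization,
                    )
                except ValueError as exc:
                    logger.warning("crosstalk %s/%s (%s) failed: %s", a, b, region, exc)
                    continue
                rows.append(
                    dict(
                        condition=cond,
                        channel_a=a,
                        channel_b=b,
                        region=region,
                        n=len(masks),
                        peak_height=peak.peak_height,
                        background=peak.background,
                        normalization=config.normalization,
                    )
                )
            if len(masks) >= 2:
                try:
                    null_avg = xt.random_pair_null(
                        [m[0] for m in masks],
                        [m[1] for m in masks],
                        seed=config.seed,
                        max_lag=config.max_lag_px,
                        normalization=config.normalization,
                        supportsA=[m[2] for m in masks],
                        supportsB=[m[2] for m in masks],
                    )
                    lag = null_avg.mean.shape[0] // 2
                    from cytoorder.correlation import Correlogram

                    mean_c = Correlogram(
                        null_avg.mean, masks[0][0].pixel_size_nm, "overlap", "cross"
                    )
                    peak = xt.peak_and_background(
                        mean_c,
                        min(config.peak_window_px, lag),
                        (min(config.bg_ring_px[0], lag - 1), min(config.bg_ring_px[1], lag)),
                    )
                    rows.append(
                        dict(
                            condition=cond,
                            channel_a=a,
                            channel_b=b,
                            region="random_pair_null",
                            n=null_avg.n,
                            peak_height=peak.peak_height,
                            background=peak.background,
                            normalization=config.normalization,
                        )
                    )
                except ValueError as exc:
                    logger.warning("random-pair null %s/%s failed: %s", a, b, exc)
    return pd.DataFrame(rows)


def _write_outputs(result: AnalysisResult, config: AnalysisConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    result.per_cell.to_csv(out / "per_cell.csv", index=False)
    result.comparisons.to_csv(out / "comparisons.csv", index=False)
    result.crosstalk_table.to_csv(out / "crosstalk.csv", index=False)
    for (cond, chan), d in result.condition_averages.items():
        rof, irof = d["rof"], d["intrinsic_rof"]
        tag = f"{cond}_{chan}".replace(" ", "_").replace("/", "-")
        frame = pd.DataFrame(
            {
                "angle_deg": np.arange(180.0),
                "rof_mean": rof.mean,
                "rof_sem": rof.sem if rof.sem is not None else np.nan,
                "intrinsic_rof_mean": irof.mean,
                "intrinsic_rof_sem": irof.sem if irof.sem is not None else np.nan,
                "n": d["n"],
            }
        )
        frame.to_csv(out / f"rof_{tag}.csv", index=False)
    with open(out / "run_summary.txt", "w") as fh:
        fh.write(
            f"processed: {result.n_processed}\nskipped: {result.n_skipped}\n"
        )
        for cid, why in result.skipped:
            fh.write(f"  skipped {cid}: {why}\n")
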