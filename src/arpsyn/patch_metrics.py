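"""Quantification of endocytic actin-patch dynamics from track tables.

Patches are cortical actin structures marked by Fim1-GFP, manually tracked
as per-frame (position, ROI intensity, cytoplasmic background) time series at
1 s intervals over 60 s movies.  From these tables the module computes the
measurements used to phenotype NPF mutants:

* peak-aligned, normalized mean intensity traces;
* assembly time (first appearance to peak intensity);
* patch initiation rate (new patches in the first 20 s, frame-1 patches
  excluded, per medial cell area);
* patch density at a frame;
* percent of patches internalized (displacement > 2 pixels among patches
  present in frame 25);
* whole-cell intensity QC (expression-level control).

Group statistics reuse :func:`arpsyn.filament_census.compare_groups`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arpsyn.filament_census import compare_groups  # noqa: F401  (shared contract)

#: Displacement threshold (pixels) for calling a patch internalized.
INTERNALIZATION_PX = 2.0

#: Frame at which patch fates are followed for percent-internalized.
FATE_FRAME = 25

#: Window (seconds) over which new-patch appearances are counted.
INITIATION_WINDOW_S = 20.0

#: Default pixel size, um per pixel.
DEFAULT_PIXEL_SIZE_UM = 0.1


@dataclass
class PatchTrack:
    """One patch's per-frame positions, ROI intensity and local background.

    Frames are 1-based, contiguous over the patch lifetime, at 1 s intervals.
    """

    patch_id: str
    frames: np.ndarray      # int, contiguous
    x: np.ndarray           # px
    y: np.ndarray           # px
    intensity: np.ndarray   # mean ROI fluorescence, a.u.
    background: np.ndarray  # per-frame cytoplasmic background, a.u.

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        for name in ("x", "y", "intensity", "background"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.frames) == 0:
            raise ValueError("empty track")
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("frames must be contiguous over the patch lifetime")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be >= 0")

    @property
    def first_frame(self) -> int:
        return int(self.frames[0])

    @property
    def last_frame(self) -> int:
        return int(self.frames[-1])

    def alive_at(self, frame: int) -> bool:
        return self.first_frame <= frame <= self.last_frame

    def corrected(self) -> np.ndarray:
        """Background-subtracted intensity trace."""
        return self.intensity - self.background

    def peak_frame(self) -> int:
        return int(self.frames[int(np.argmax(self.corrected()))])


@dataclass
class CellRecord:
    """One cell's tracks plus the per-cell metadata the metrics need."""

    cell_id: str
    tracks: list[PatchTrack]
    medial_area_um2: float
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    movie_duration_s: float = 60.0
    strain: str = ""
    whole_cell_intensity: float = np.nan
    extracellular_background: float = np.nan

    def __post_init__(self) -> None:
        if not self.medial_area_um2 > 0:
            raise ValueError("cell area must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel size must be positive")


# ---------------------------------------------------------------------------
# Per-track measurements
# ---------------------------------------------------------------------------

def appearance_frame(track: PatchTrack) -> int:
    """First frame whose background-subtracted intensity clears noise.

    The appearance threshold is twice the standard deviation of the track's
    recorded cytoplasmic background (the noise floor available to a manual
    tracker); if no frame clears it, the track's first frame is returned.
    """
    corrected = track.corrected()
    sd = float(np.std(track.background))
    above = np.nonzero(corrected > 2.0 * sd)[0]
    if len(above) == 0:
        return track.first_frame
    return int(track.frames[above[0]])


def assembly_time(track: PatchTrack) -> float:
    """Seconds from first appearance to peak background-subtracted intensity."""
    corrected = track.corrected()
    if not np.any(corrected > 0):
        raise ValueError(f"track {track.patch_id} has no positive intensity")
    t_peak = track.peak_frame()
    t_first = appearance_frame(track)
    if t_peak <= t_first:
        warnings.warn(
            f"track {track.patch_id}: peak at first appearance; assembly time 0",
            stacklevel=2,
        )
        return 0.0
    return float(t_peak - t_first)


def assembly_times(cells: "list[CellRecord] | list[PatchTrack]") -> pd.DataFrame:
    """Assembly times for all tracks whose assembly was fully observed.

    Tracks already present in frame 1 (appearance unobserved) and tracks
    whose intensity is still rising at their last frame (peak possibly
    truncated) are excluded; including them would bias the mean short.
    Returns columns patch_id, strain, assembly_s.
    """
    pairs: list[tuple[str, PatchTrack]] = []
    for item in cells:
        if isinstance(item, PatchTrack):
            pairs.append(("", item))
        else:
            pairs.extend((item.strain, tr) for tr in item.tracks)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for strain, tr in pairs:
            if tr.first_frame <= 1 or tr.peak_frame() >= tr.last_frame:
                continue
            try:
                rows.append({"patch_id": tr.patch_id, "strain": strain,
                             "assembly_s": assembly_time(tr)})
            except ValueError:
                continue
    return pd.DataFrame(rows, columns=["patch_id", "strain", "assembly_s"])


def aligned_mean_trace(
    tracks: list[PatchTrack],
    reference_peak: float,
) -> pd.DataFrame:
    """Peak-aligned, normalized mean intensity trace across patches.

    Each track is background subtracted, shifted so its peak sits at time 0,
    and normalized by ``reference_peak`` (the wild-type mean peak value).
    Returns columns offset_s, mean, sd, n.
    """
    if not tracks:
        raise ValueError("need at least one track")
    if not reference_peak > 0:
        raise ValueError("reference peak must be positive")
    per_offset: dict[int, list[float]] = {}
    for tr in tracks:
        corrected = tr.corrected()
        if not np.any(corrected > 0):
            raise ValueError(f"track {tr.patch_id} has no positive intensity")
        peak = tr.peak_frame()
        for f, v in zip(tr.frames, corrected):
            per_offset.setdefault(int(f - peak), []).append(v / reference_peak)
    rows = []
    for off in sorted(per_offset):
        vals = np.array(per_offset[off])
        rows.append({
            "offset_s": float(off),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=0)) if len(vals) > 1 else 0.0,
            "n": len(vals),
        })
    return pd.DataFrame(rows)


def max_displacement(track: PatchTrack) -> float:
    """Largest distance (px) from the patch's pre-peak mean position."""
    pre = track.frames <= track.peak_frame()
    x0 = track.x[pre].mean()
    y0 = track.y[pre].mean()
    return float(np.hypot(track.x - x0, track.y - y0).max())


# ---------------------------------------------------------------------------
# Per-cell measurements
# ---------------------------------------------------------------------------

def initiation_rate(cell: CellRecord) -> float:
    """New patches per um^2 per second over the movie's first 20 s.

    Counts patches first seen in frames 2..21 (patches already present in
    frame 1 are excluded) and divides by medial area and 20 s.
    """
    if cell.movie_duration_s < INITIATION_WINDOW_S + 1:
        raise ValueError("movie must cover at least 21 frames")
    n_new = sum(
        1 for tr in cell.tracks
        if 1 < tr.first_frame <= 1 + INITIATION_WINDOW_S
    )
    return n_new / (cell.medial_area_um2 * INITIATION_WINDOW_S)


def patch_density(cell: CellRecord, frame: int) -> float:
    """Patches present at ``frame`` per um^2 of medial cell area."""
    n = sum(1 for tr in cell.tracks if tr.alive_at(frame))
    return n / cell.medial_area_um2


def percent_internalized(cell: CellRecord, fate_frame: int = FATE_FRAME) -> float:
    """Percent of patches present at the fate frame that internalize.

    A patch internalizes if it moves more than 2 pixels from its pre-peak
    mean position at any point in its lifetime.
    """
    present = [tr for tr in cell.tracks if tr.alive_at(fate_frame)]
    if not present:
        raise ValueError(
            f"cell {cell.cell_id}: no patches present in frame {fate_frame}; "
            "percent internalized undefined"
        )
    n_int = sum(1 for tr in present if max_displacement(tr) > INTERNALIZATION_PX)
    return 100.0 * n_int / len(present)


def whole_cell_qc(cells: list[CellRecord]) -> pd.DataFrame:
    """Per-strain mean background-subtracted whole-cell intensity.

    Tracks tagged-protein expression levels so strains within a dataset can
    be confirmed comparable.
    """
    df = pd.DataFrame([
        {"strain": c.strain,
         "level": c.whole_cell_intensity - c.extracellular_background}
        for c in cells
    ])
    out = df.groupby("strain")["level"].agg(["mean", "sem", "count"])
    return out.rename(columns={"count": "n"}).reset_index()


def cell_metrics(cells: list[CellRecord]) -> pd.DataFrame:
    """Per-cell table of initiation rate, density and percent internalized."""
    rows = []
    for cell in cells:
        row = {
            "cell_id": cell.cell_id, "strain": cell.strain,
            "initiation_rate_per_um2_s": initiation_rate(cell),
            "density_frame1_per_um2": patch_density(cell, 1),
        }
        try:
            row["percent_internalized"] = percent_internalized(cell)
        except ValueError:
            row["percent_internalized"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_TRACK_COLS = ["cell_id", "patch_id", "frame", "t_s", "x_px", "y_px",
               "intensity", "background"]
_CELL_COLS = ["cell_id", "strain", "medial_area_um2", "pixel_size_um",
              "movie_duration_s", "whole_cell_intensity",
              "extracellular_background"]


def write_cells(cells: list[CellRecord], tracks_path, cells_path) -> None:
    track_rows = []
    for cell in cells:
        for tr in cell.tracks:
            for i, f in enumerate(tr.frames):
                track_rows.append([cell.cell_id, tr.patch_id, int(f), float(f - 1),
                                   tr.x[i], tr.y[i], tr.intensity[i], tr.background[i]])
    pd.DataFrame(track_rows, columns=_TRACK_COLS).to_csv(
        tracks_path, sep="\t", index=False, float_format="%.4f")
    cell_rows = [[c.cell_id, c.strain, c.medial_area_um2, c.pixel_size_um,
                  c.movie_duration_s, c.whole_cell_intensity,
                  c.extracellular_background] for c in cells]
    pd.DataFrame(cell_rows, columns=_CELL_COLS).to_csv(
        cells_path, sep="\t", index=False, float_format="%.4f")


def read_cells(tracks_path, cells_path) -> list[CellRecord]:
    tracks_df = pd.read_csv(tracks_path, sep="\t")
    cells_df = pd.read_csv(cells_path, sep="\t")
    by_cell: dict[str, list[PatchTrack]] = {}
    for (cell_id, patch_id), grp in tracks_df.groupby(["cell_id", "patch_id"],
                                                      sort=False):
        grp = grp.sort_values("frame")
        by_cell.setdefault(str(cell_id), []).append(PatchTrack(
            str(patch_id), grp.frame.to_numpy(), grp.x_px.to_numpy(),
            grp.y_px.to_numpy(), grp.intensity.to_numpy(),
            grp.background.to_numpy()))
    cells = []
    for row in cells_df.itertuples(index=False):
        cells.append(CellRecord(
            str(row.cell_id), by_cell.get(str(row.cell_id), []),
            float(row.medial_area_um2), float(row.pixel_size_um),
            float(row.movie_duration_s), str(row.strain),
            float(row.whole_cell_intensity), float(row.extracellular_background)))
    return cells
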