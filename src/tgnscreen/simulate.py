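"""Synthetic fluorescence fields and simulated screens with ground truth.

The real assay images four channels per field — a nuclear stain, a
cell-body/cytoskeleton stain, a trans-Golgi network (TGN) marker and a
cargo-protein stain — and reads out how strongly the cargo is retained in
the TGN.  This module fabricates such fields with a fully known geometry
and cargo split, plus whole simulated screens and dose titrations, so that
every downstream stage (segmentation, ratio quantification, plate QC, hit
triage, curve fitting, profiling) can be tested without any raw data.

Ground truth is explicit: every generated cell carries its designed
inside/outside cargo budget and hence its designed translocation ratio,
and every simulated compound carries a hidden active/toxic label.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DOSE_GRID_UM",
    "FieldSpec",
    "FieldImage",
    "GroundTruth",
    "ScreenSpec",
    "generate_field",
    "generate_screen",
    "generate_titration",
    "four_param_logistic",
    "cargo_fraction_for_ratio",
]

#: Eleven-point counter-screen dose grid, in µM (two-fold steps, 40 nM–40 µM).
DOSE_GRID_UM: tuple[float, ...] = (
    0.04, 0.08, 0.16, 0.31, 0.63, 1.25, 2.5, 5.0, 10.0, 20.0, 40.0,
)


def four_param_logistic(x, bottom: float, top: float, ec50: float, hill: float):
    """Four-parameter logistic response at dose ``x``.

    ``y = bottom + (top - bottom) / (1 + (x / ec50)**hill)``.

    With ``hill > 0`` the curve decreases monotonically from ``top`` (at
    zero dose) to ``bottom`` (at saturating dose); EC50 is the dose of
    half-maximal effect.
    """
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + (x / ec50) ** hill)


def cargo_fraction_for_ratio(ratio: float, tgn_area: float, cyto_area: float) -> float:
    """Fraction of total cargo to place inside the TGN so that the ratio of
    mean intensities (inside / outside) equals ``ratio``.

    Solves ``ratio = (f/A_tgn) / ((1-f)/A_cyto)`` for ``f``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    q = ratio * tgn_area / cyto_area
    return q / (1.0 + q)


# ---------------------------------------------------------------------------
# Field simulation
# ---------------------------------------------------------------------------

@dataclass
class FieldSpec:
    """Parameters of one synthetic imaging field.

    Geometry emulates a monolayer of adherent cells: elliptical cell
    bodies, one round nucleus each, and one compact perinuclear TGN blob
    per cell.  The cargo channel places ``cargo_tgn_fraction`` of each
    cell's total cargo intensity uniformly over its TGN mask and spreads
    the remainder over the cytoplasm as diffuse signal plus puncta; the
    mean-intensity ratio inside/outside the TGN is therefore known exactly
    per cell.  If ``target_ratio`` is set it overrides
    ``cargo_tgn_fraction`` cell by cell, using the realised mask areas, so
    the designed ratio is hit exactly.
    """

    image_size: tuple[int, int] = (512, 512)
    pixel_size: float = 0.65            # µm per pixel (20x objective scale)
    n_cells: int = 25
    cell_radius_range: tuple[float, float] = (28.0, 40.0)   # pixels
    nucleus_radius_fraction: float = 0.35
    tgn_area_fraction: float = 0.08     # of cell area
    cargo_tgn_fraction: float = 0.6     # of the cell's total cargo intensity
    target_ratio: float | None = None   # designed mean-intensity ratio
    puncta_count_mean: float = 30.0
    puncta_intensity_fraction: float = 0.4  # share of outside budget in puncta
    cargo_total: float = 2.0e5          # intensity budget per cell
    nucleus_level: float = 800.0
    body_level: float = 400.0
    tgn_level: float = 900.0
    background_level: float = 100.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if h <= 0 or w <= 0:
            raise ValueError("image_size must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("nucleus_radius_fraction", "tgn_area_fraction",
                     "cargo_tgn_fraction"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cell_radius_range[0] > self.cell_radius_range[1]:
            raise ValueError("cell_radius_range must be (lo, hi) with lo <= hi")
        if self.target_ratio is not None and self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


@dataclass
class FieldImage:
    """One imaged site: four co-registered 2D channels plus pixel size.

    Channel order is fixed: nucleus, cell body, TGN marker, cargo.
    """

    nucleus: np.ndarray
    body: np.ndarray
    tgn: np.ndarray
    cargo: np.ndarray
    pixel_size: float = 0.65

    CHANNEL_ORDER = ("nucleus", "body", "tgn", "cargo")

    def stack(self) -> np.ndarray:
        """Channels as a (4, H, W) array in :attr:`CHANNEL_ORDER`."""
        return np.stack([self.nucleus, self.body, self.tgn, self.cargo])

    @classmethod
    def from_stack(cls, stack: np.ndarray, pixel_size: float = 0.65) -> "FieldImage":
        if stack.ndim != 3 or stack.shape[0] != 4:
            raise ValueError("expected a (4, H, W) channel stack")
        return cls(*[np.asarray(c, dtype=float) for c in stack],
                   pixel_size=pixel_size)


@dataclass
class GroundTruth:
    """Designed masks and per-cell cargo split for a synthetic field.

    ``cells`` has one row per cell: label, designed inside/outside cargo
    totals, mask areas (pixels), the implied designed mean-intensity ratio,
    and whether the cell was clipped by the field border (never, with the
    default rejection-sampled placement).
    """

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    tgn_labels: np.ndarray
    cells: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cell_id", "cargo_in", "cargo_out", "tgn_area",
                 "cyto_area", "cell_area", "designed_ratio", "clipped"]))


def _ellipse_mask(shape, center, a, b, theta):
    """Boolean mask of a filled rotated ellipse (semi-axes a, b)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _disk_mask(shape, center, r):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r * r


def _place_cells(spec: FieldSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping cell centers fully inside the field."""
    h, w = spec.image_size
    if 2 * spec.cell_radius_range[1] + 4 > min(h, w):
        raise ValueError("cell_radius_range too large for image_size")
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    max_attempts = 4000 * max(spec.n_cells, 1)
    while len(centers) < spec.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells in a "
                f"{h}x{w} field; reduce n_cells or cell radius")
        r = rng.uniform(*spec.cell_radius_range)
        cy = rng.uniform(r + 1, h - r - 2)
        cx = rng.uniform(r + 1, w - r - 2)
        ok = all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 2) ** 2
                 for (y, x), rr in zip(centers, radii))
        if ok:
            centers.append((cy, cx))
            radii.append(r)
    return centers, radii


def generate_field(spec: FieldSpec) -> tuple[FieldImage, GroundTruth]:
    """Render one synthetic 4-channel field with full ground truth.

    Deterministic given ``spec.seed``.  Noise is additive Gaussian per
    channel (clipped at zero); with ``noise_sd = 0`` the designed per-cell
    ratio is exact up to pixel discretisation of the masks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    shape = (h, w)

    nucleus_ch = np.full(shape, spec.background_level, dtype=float)
    body_ch = np.full(shape, spec.background_level, dtype=float)
    tgn_ch = np.full(shape, spec.background_level, dtype=float)
    cargo_ch = np.full(shape, spec.background_level, dtype=float)

    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    tgn_labels = np.zeros(shape, dtype=np.int32)

    rows = []
    if spec.n_cells > 0:
        centers, radii = _place_cells(spec, rng)
        for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
            theta = rng.uniform(0, np.pi)
            a = r
            b = r * rng.uniform(0.85, 1.0)
            cell = _ellipse_mask(shape, (cy, cx), a, b, theta) & (cell_labels == 0)
            nuc_r = spec.nucleus_radius_fraction * b
            nuc = _disk_mask(shape, (cy, cx), nuc_r) & cell

            cell_area = int(cell.sum())
            tgn_r = np.sqrt(spec.tgn_area_fraction * cell_area / np.pi)
            # perinuclear placement: TGN disk hugs the nucleus, inside the cell
            ang = rng.uniform(0, 2 * np.pi)
            d = nuc_r + 0.8 * tgn_r
            tgn = _disk_mask(shape, (cy + d * np.sin(ang), cx + d * np.cos(ang)),
                             tgn_r) & cell

            cyto = cell & ~tgn
            tgn_area = int(tgn.sum())
            cyto_area = int(cyto.sum())
            if tgn_area == 0 or cyto_area == 0:  # pragma: no cover - geometry guard
                continue

            if spec.target_ratio is not None:
                f_in = cargo_fraction_for_ratio(spec.target_ratio, tgn_area,
                                                cyto_area)
            else:
                f_in = spec.cargo_tgn_fraction
            cargo_in = f_in * spec.cargo_total
            cargo_out = (1.0 - f_in) * spec.cargo_total

            nucleus_ch[nuc] += spec.nucleus_level
            body_ch[cell] += spec.body_level
            tgn_ch[tgn] += spec.tgn_level
            cargo_ch[tgn] += cargo_in / tgn_area

            # outside budget: diffuse floor plus bright puncta; the mean over
            # the cytoplasm mask is exact regardless of the split
            punct_budget = spec.puncta_intensity_fraction * cargo_out
            cargo_ch[cyto] += (cargo_out - punct_budget) / cyto_area
            n_punct = rng.poisson(spec.puncta_count_mean)
            if n_punct > 0 and punct_budget > 0:
                idx = np.flatnonzero(cyto)
                chosen = rng.choice(idx, size=min(n_punct, idx.size),
                                    replace=False)
                per = punct_budget / chosen.size
                np.add.at(cargo_ch.ravel(), chosen, per)
            else:
                cargo_ch[cyto] += punct_budget / cyto_area

            nucleus_labels[nuc] = i
            cell_labels[cell] = i
            tgn_labels[tgn] = i
            rows.append({
                "cell_id": i,
                "cargo_in": cargo_in,
                "cargo_out": cargo_out,
                "tgn_area": tgn_area,
                "cyto_area": cyto_area,
                "cell_area": cell_area,
                "designed_ratio": (cargo_in / tgn_area) / (cargo_out / cyto_area),
                "clipped": False,
            })

    if spec.noise_sd > 0:
        for ch in (nucleus_ch, body_ch, tgn_ch, cargo_ch):
            ch += rng.normal(0.0, spec.noise_sd, size=shape)
            np.clip(ch, 0.0, None, out=ch)

    truth = GroundTruth(nucleus_labels, cell_labels, tgn_labels,
                        pd.DataFrame(rows))
    img = FieldImage(nucleus_ch, body_ch, tgn_ch, cargo_ch,
                     pixel_size=spec.pixel_size)
    return img, truth


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------

@dataclass
class ScreenSpec:
    """Parameters of a simulated single-concentration screen.

    Per-well mean ratios are drawn directly at well level (image rendering
    is reserved for the imaging tests): negative-control and untreated
    compound wells from ``Normal(neg_ratio_mean, neg_ratio_sd)``,
    positive controls from ``Normal(pos_ratio_mean, pos_ratio_sd)``.
    Defaults reproduce the fibroblast assay's control separation
    (patient 1.34 ± 0.05 vs carrier 1.10 ± 0.02 ratio units) and the
    observed screen composition (1.7% active, 5.0% toxic compounds).
    Active compounds shift the ratio down by ``active_effect_sd_units``
    negative-control SDs; toxic compounds shift the well cell count down
    by ``toxic_effect_sd_units`` cell-count SDs.  A per-plate additive
    ratio shift models inter-plate variability.
    """

    n_plates: int = 8
    wells_per_plate: int = 384
    n_neg_ctrl: int = 16
    n_pos_ctrl: int = 16
    neg_ratio_mean: float = 1.34
    neg_ratio_sd: float = 0.05
    pos_ratio_mean: float = 1.10
    pos_ratio_sd: float = 0.02
    cellcount_mean: float = 300.0
    cellcount_sd: float = 30.0
    active_fraction: float = 0.017
    toxic_fraction: float = 0.05
    active_effect_sd_units: float = 5.0
    toxic_effect_sd_units: float = 3.0
    plate_shift_sd: float = 0.01
    concentration_uM: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.wells_per_plate < self.n_neg_ctrl + self.n_pos_ctrl:
            raise ValueError("controls exceed plate capacity")
        for name in ("active_fraction", "toxic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("neg_ratio_sd", "pos_ratio_sd", "cellcount_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")

    @property
    def compounds_per_plate(self) -> int:
        return self.wells_per_plate - self.n_neg_ctrl - self.n_pos_ctrl

    @property
    def n_compounds(self) -> int:
        return self.n_plates * self.compounds_per_plate


def _well_ids(n: int, n_cols: int = 24) -> list[str]:
    rows = "ABCDEFGHIJKLMNOP"
    ids = []
    for i in range(n):
        r, c = divmod(i, n_cols)
        ids.append(f"{rows[r % len(rows)]}{c + 1:02d}")
    return ids


def generate_screen(spec: ScreenSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a whole screen; returns ``(wells, truth)``.

    ``wells`` has one row per well with columns ``plate, well, role,
    compound_id, concentration_uM, ratio, cell_count``.  ``truth`` has the
    hidden per-compound labels (``compound_id, active, toxic``) and is
    never consulted by the analysis stages — it exists so tests can score
    recovery.  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_cmpd = spec.n_compounds
    active = rng.random(n_cmpd) < spec.active_fraction
    toxic = rng.random(n_cmpd) < spec.toxic_fraction
    compound_ids = [f"C{i + 1:06d}" for i in range(n_cmpd)]
    truth = pd.DataFrame({"compound_id": compound_ids,
                          "active": active, "toxic": toxic})

    rows = []
    cmpd_cursor = 0
    for p in range(1, spec.n_plates + 1):
        plate_id = f"P{p:03d}"
        shift = rng.normal(0.0, spec.plate_shift_sd) if spec.plate_shift_sd > 0 else 0.0
        well_ids = _well_ids(spec.wells_per_plate)
        roles = (["negative_control"] * spec.n_neg_ctrl
                 + ["positive_control"] * spec.n_pos_ctrl
                 + ["compound"] * spec.compounds_per_plate)
        for well, role in zip(well_ids, roles):
            count = rng.normal(spec.cellcount_mean, spec.cellcount_sd)
            if role == "negative_control":
                ratio = rng.normal(spec.neg_ratio_mean, spec.neg_ratio_sd)
                cid, conc = "", np.nan
            elif role == "positive_control":
                ratio = rng.normal(spec.pos_ratio_mean, spec.pos_ratio_sd)
                cid, conc = "", np.nan
            else:
                cid = compound_ids[cmpd_cursor]
                conc = spec.concentration_uM
                mean = spec.neg_ratio_mean
                if active[cmpd_cursor]:
                    mean -= spec.active_effect_sd_units * spec.neg_ratio_sd
                ratio = rng.normal(mean, spec.neg_ratio_sd)
                if toxic[cmpd_cursor]:
                    count -= spec.toxic_effect_sd_units * spec.cellcount_sd
                cmpd_cursor += 1
            rows.append({
                "plate": plate_id, "well": well, "role": role,
                "compound_id": cid, "concentration_uM": conc,
                "ratio": ratio + shift,
                "cell_count": max(int(round(count)), 0),
            })
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Titration simulation
# ---------------------------------------------------------------------------

def generate_titration(bottom: float, top: float, ec50: float, hill: float,
                       doses=DOSE_GRID_UM, noise_sd: float = 0.0,
                       replicates: int = 2, seed: int = 0) -> pd.DataFrame:
    """Simulate a replicated dose titration from a 4PL ground truth.

    Responses are ``4PL(dose) + Normal(0, noise_sd)`` per replicate, on
    whatever scale the 4PL parameters are given (typically z-score units).
    The default dose grid is the 11-point counter-screen series
    (0.04–40 µM).  Deterministic given ``seed``.
    """
    doses = np.asarray(list(doses), dtype=float)
    if doses.size == 0:
        raise ValueError("dose list must not be empty")
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, replicates + 1):
        y = four_param_logistic(doses, bottom, top, ec50, hill)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=doses.size)
        for d, v in zip(doses, y):
            rows.append({"dose_uM": d, "replicate": rep, "response": v})
    return pd.DataFrame(rows)
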