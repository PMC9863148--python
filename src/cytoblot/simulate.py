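"""Synthetic membranes and expression tables with known ground truth.

The generator emulates the pooled-urine membrane-array study design: two
experiment series, each with one membrane per arm (male/female x
CKD/control, every membrane a pool of ten urine samples), duplicate spots
per analyte, corner reference spots, log-normal analyte abundances, a
planted set of up/down-regulated marker analytes shared between series, and
optional series-discordant markers.  Images are rendered as sums of
Gaussian spots on a constant background with read noise, with the spot
lattice perturbed by a corner-anchored bilinear warp plus per-spot jitter;
a fraction of spots can be absent entirely.

Every output carries a :class:`GroundTruth` sidecar sufficient to score
grid recovery, detection, differential expression and panel consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gridfit import SpotGrid, _unit_coordinates
from .imaging import MembraneImage
from .layout import ArrayLayout
from .quantify import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "StudySimulation",
    "default_layout",
    "simulate_membrane",
    "simulate_study",
    "simulate_expression_table",
    "true_grid",
]

Arm = tuple[int, str, str]  # (series, gender, group)


def default_layout() -> ArrayLayout:
    """The bundled synthetic membrane design: 2x2 blocks of 10x10 spots.

    Duplicates sit in adjacent columns (pairs (0,1), (2,3), ...).  A single
    reference spot sits at each extreme grid corner (its pair-mate is left
    empty, so each corner anchor is unambiguous); two pairs per block are
    negative controls; 50 analytes (``A01``..``A50``) are distributed
    round-robin over the blocks; the remaining pairs are empty.
    """
    n_br = n_bc = 2
    rows, cols = 10, 10
    ref_pairs = {  # (block_row, block_col, row, pair_col_start)
        (0, 0, 0, 0), (0, 1, 0, 8), (1, 0, 9, 0), (1, 1, 9, 8),
    }
    ref_spots = {  # the exact corner positions within those pairs
        (0, 0, 0, 0), (0, 1, 0, 9), (1, 0, 9, 0), (1, 1, 9, 9),
    }
    # enumerate non-reference pairs per block in deterministic order
    block_pairs: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for br in range(n_br):
        for bc in range(n_bc):
            pairs = [
                (r, c0)
                for r in range(rows)
                for c0 in range(0, cols, 2)
                if (br, bc, r, c0) not in ref_pairs
            ]
            block_pairs[(br, bc)] = pairs

    assignment: dict[tuple[int, int, int, int], tuple[str, str]] = {}
    blocks = [(0, 0), (0, 1), (1, 0), (1, 1)]
    cursor = {b: 0 for b in blocks}
    for i in range(50):
        b = blocks[i % 4]
        r, c0 = block_pairs[b][cursor[b]]
        cursor[b] += 1
        assignment[(*b, r, c0)] = (f"A{i + 1:02d}", "analyte")
    for b in blocks:  # two negative-control pairs per block
        for _ in range(2):
            r, c0 = block_pairs[b][cursor[b]]
            cursor[b] += 1
            assignment[(*b, r, c0)] = ("NEG", "negative")

    positions = []
    for br in range(n_br):
        for bc in range(n_bc):
            for r in range(rows):
                for c in range(cols):
                    if (br, bc, r, c) in ref_spots:
                        analyte, role = "REF", "reference"
                    else:
                        c0 = c - (c % 2)
                        analyte, role = assignment.get((br, bc, r, c0), ("", "empty"))
                    positions.append((br, bc, r, c, analyte, role))
    return ArrayLayout(
        name="synthetic-2x2x10x10",
        n_block_rows=n_br, n_block_cols=n_bc,
        rows_per_block=rows, cols_per_block=cols,
        pitch=18.0, alley_row=1.0, alley_col=1.0, spot_radius=6.0,
        positions=tuple(positions),
    ).check_valid()


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic membrane experiment.

    Defaults reproduce the emulated study: 2 series x {M, F} x
    {CKD, control} (one pooled membrane per arm), log-normal analyte
    abundances (log2 mean 15, SD 1), 4 up- and 4 down-regulated consensus
    markers at 3-fold change, duplicate technical CV 15%, Gaussian spot PSF
    sigma 2.5 px, corner jitter SD 2 px, per-spot jitter SD 1 px, constant
    background 50 with read-noise SD 10 on a 600x400 16-bit raster.
    """

    layout: ArrayLayout = field(default_factory=default_layout)
    series: tuple[int, ...] = (1, 2)
    genders: tuple[str, ...] = ("M", "F")
    groups: tuple[str, ...] = ("ckd", "control")
    baseline_log2_mean: float = 15.0
    baseline_log2_sd: float = 1.0
    n_planted_up: int = 4
    n_planted_down: int = 4
    fold_change: float = 3.0
    planted_markers: tuple[tuple[str, str], ...] | None = None
    discordant_markers: tuple[str, ...] = ()
    blank_analytes: tuple[str, ...] = ()
    technical_cv: float = 0.15
    membrane_scale_sd: float = 0.0
    psf_sigma: float = 2.5
    corner_jitter_sd: float = 2.0
    spot_jitter_sd: float = 1.0
    missing_spot_prob: float = 0.0
    background_level: float = 50.0
    read_noise_sd: float = 10.0
    reference_log2: float = 21.0
    image_height: int = 400
    image_width: int = 600
    seed: int = 0

    def __post_init__(self):
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if not 0 <= self.missing_spot_prob <= 1:
            raise ValueError("missing_spot_prob must be in [0, 1]")
        if self.technical_cv < 0 or self.membrane_scale_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        # excessive jitter would collide adjacent spots
        if self.spot_jitter_sd * 4 > self.layout.pitch / 2:
            raise ValueError("spot jitter too large for the layout pitch")

    def planted(self) -> dict[str, str]:
        """Resolve the planted marker map (analyte -> direction)."""
        if self.planted_markers is not None:
            return dict(self.planted_markers)
        analytes = self.layout.analytes
        n = self.n_planted_up + self.n_planted_down
        if n > len(analytes):
            raise ValueError("more planted markers than analytes")
        # deterministic, spread across the analyte list
        idx = np.linspace(0, len(analytes) - 1, n).round().astype(int)
        chosen = [analytes[i] for i in idx]
        return {
            **{a: "up" for a in chosen[: self.n_planted_up]},
            **{a: "down" for a in chosen[self.n_planted_up:]},
        }

    def arms(self) -> list[Arm]:
        return [
            (s, g, grp)
            for s in self.series
            for g in self.genders
            for grp in self.groups
        ]


@dataclass
class GroundTruth:
    """Truth sidecar for one simulated membrane.

    ``spots``: per-position DataFrame (keys, analyte, role, true_x, true_y,
    true_signal = integrated spot mass excluding background, present flag).
    ``analyte_means``: noiseless expected integrated signal per analyte for
    this arm; ``planted``: direction of each planted marker in this series.
    """

    arm: Arm
    spots: pd.DataFrame
    analyte_means: dict[str, float]
    planted: dict[str, str]
    corners_true: tuple[tuple[float, float], ...]

    def to_tsv(self, path: str | Path) -> None:
        self.spots.to_csv(path, sep="\t", index=False, float_format="%.9g")


def _series_direction(direction: str, series: int, discordant: bool) -> str:
    """Planted direction in a given series; discordant markers flip in even series."""
    if discordant and series % 2 == 0:
        return "down" if direction == "up" else "up"
    return direction


def _baselines(config: SimulationConfig) -> dict[str, float]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBA5E]))
    analytes = config.layout.analytes
    draws = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                              size=len(analytes))
    base = dict(zip(analytes, draws))
    for a in config.blank_analytes:
        base[a] = 0.0
    return base


def arm_means(config: SimulationConfig, arm: Arm) -> dict[str, float]:
    """Expected integrated signal per analyte for one study arm."""
    series, _gender, group = arm
    base = _baselines(config)
    planted = config.planted()
    out = {}
    for a, b in base.items():
        m = b
        if group == "ckd" and a in planted:
            d = _series_direction(planted[a], series,
                                  a in config.discordant_markers)
            m = b * config.fold_change if d == "up" else b / config.fold_change
        out[a] = m
    return out


def _arm_rng(config: SimulationConfig, arm: Arm) -> np.random.Generator:
    series, gender, group = arm
    key = [config.seed, series,
           int.from_bytes(gender.encode(), "little") % (2**31),
           int.from_bytes(group.encode(), "little") % (2**31)]
    return np.random.default_rng(np.random.SeedSequence(key))


def _ideal_corners(config: SimulationConfig) -> np.ndarray:
    lay = config.layout
    span_x = ((lay.n_block_cols - 1) * (lay.cols_per_block + lay.alley_col)
              + (lay.cols_per_block - 1)) * lay.pitch
    span_y = ((lay.n_block_rows - 1) * (lay.rows_per_block + lay.alley_row)
              + (lay.rows_per_block - 1)) * lay.pitch
    mx = (config.image_width - span_x) / 2.0
    my = (config.image_height - span_y) / 2.0
    if mx < 4 * config.psf_sigma or my < 4 * config.psf_sigma:
        raise ValueError("layout span does not fit the configured image size")
    return np.array([
        [mx, my],                      # TL
        [mx + span_x, my],             # TR
        [mx, my + span_y],             # BL
        [mx + span_x, my + span_y],    # BR
    ])


def _warp(uv: tuple[float, float], corners: np.ndarray) -> np.ndarray:
    u, v = uv
    tl, tr, bl, br = corners
    return (1 - u) * (1 - v) * tl + u * (1 - v) * tr + (1 - u) * v * bl + u * v * br


def _cv_sigma_ln(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def simulate_membrane(
    config: SimulationConfig, arm: Arm, rng: np.random.Generator | None = None
) -> tuple[MembraneImage, GroundTruth]:
    """Render one membrane image for a study arm, with its truth sidecar.

    The image is the sum of Gaussian spots (integrated mass = the analyte's
    expected signal perturbed by duplicate technical noise; PSF sigma from
    the config) at bilinearly warped grid positions, plus constant
    background and Gaussian read noise.  Reference spots sit exactly at the
    (jittered) grid corners at a fixed high intensity and are never absent.
    """
    if rng is None:
        rng = _arm_rng(config, arm)
    lay = config.layout
    means = arm_means(config, arm)
    sigma_ln = _cv_sigma_ln(config.technical_cv)
    scale = 2.0 ** rng.normal(0.0, config.membrane_scale_sd) if config.membrane_scale_sd else 1.0

    corners = _ideal_corners(config)
    corners_true = corners + rng.normal(0.0, config.corner_jitter_sd, size=(4, 2))

    uv = _unit_coordinates(lay)
    h, w = config.image_height, config.image_width
    img = np.full((h, w), config.background_level, dtype=np.float64)
    psf = config.psf_sigma
    norm = 2.0 * np.pi * psf * psf

    rows = []
    ref_mass = 2.0 ** config.reference_log2
    is_corner_uv = {k for k, (u, v) in uv.items() if (u in (0.0, 1.0)) and (v in (0.0, 1.0))}
    for br, bc, r, c, analyte, role in lay.positions:
        key = (br, bc, r, c)
        p = _warp(uv[key], corners_true)
        jitter = rng.normal(0.0, config.spot_jitter_sd, size=2)
        present = True
        if role == "analyte":
            mass = means[analyte] * scale
            if sigma_ln > 0 and mass > 0:
                mass *= np.exp(rng.normal(0.0, sigma_ln))
        elif role == "reference":
            mass = ref_mass
        else:
            mass = 0.0
        if role != "reference" and config.missing_spot_prob > 0:
            if rng.random() < config.missing_spot_prob:
                present = False
        # jitter models printing imprecision of physical spots: a position
        # with nothing printed has its true centre on the warped lattice
        if present and mass > 0 and key not in is_corner_uv:
            p = p + jitter
        if present and mass > 0:
            _render_spot(img, p[0], p[1], mass / norm, psf)
        rows.append((br, bc, r, c, analyte, role, p[0], p[1],
                     mass if present else 0.0, present))

    if config.read_noise_sd > 0:
        img += rng.normal(0.0, config.read_noise_sd, size=img.shape)
    np.clip(img, 0.0, 65535.0, out=img)

    spots = pd.DataFrame(rows, columns=[
        "block_row", "block_col", "row", "col", "analyte", "role",
        "true_x", "true_y", "true_signal", "present",
    ])
    truth = GroundTruth(
        arm=arm, spots=spots, analyte_means=means,
        planted={a: _series_direction(d, arm[0], a in config.discordant_markers)
                 for a, d in config.planted().items()},
        corners_true=tuple(map(tuple, corners_true)),
    )
    return MembraneImage(img), truth


def _render_spot(img: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    h, w = img.shape
    r = int(np.ceil(5 * sigma))
    x0, x1 = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0, y1 = max(int(y) - r, 0), min(int(y) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)[:, None]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((xs - x) ** 2 + (ys - y) ** 2) / (2.0 * sigma * sigma)
    )


def true_grid(truth: GroundTruth) -> SpotGrid:
    """SpotGrid at the planted spot centres (for stages downstream of gridding)."""
    entries = {
        (int(t.block_row), int(t.block_col), int(t.row), int(t.col)):
            (float(t.true_x), float(t.true_y), "snapped")
        for t in truth.spots.itertuples()
    }
    return SpotGrid(entries=entries, corners=truth.corners_true)


@dataclass
class StudySimulation:
    """All membranes of a simulated study plus the planted truth."""

    config: SimulationConfig
    membranes: dict[Arm, tuple[MembraneImage, GroundTruth]]
    manifest: pd.DataFrame

    def truth_consensus(self, gender: str | None = None) -> dict[str, str]:
        """Markers planted with the same direction in every series.

        Discordant markers flip between series and therefore drop out.
        """
        planted = self.config.planted()
        out = {}
        for a, d in planted.items():
            dirs = {
                _series_direction(d, s, a in self.config.discordant_markers)
                for s in self.config.series
            }
            if len(dirs) == 1:
                out[a] = dirs.pop()
        return out

    def write(self, directory: str | Path) -> pd.DataFrame:
        from .imaging import write_image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for arm, (img, truth) in self.membranes.items():
            s, g, grp = arm
            stem = f"s{s}_{g}_{grp}"
            write_image(img, directory / f"{stem}.tif")
            truth.to_tsv(directory / f"{stem}_truth.tsv")
            rows.append((s, g, grp, f"{stem}.tif", f"{stem}_truth.tsv"))
        manifest = pd.DataFrame(rows, columns=["series", "gender", "group", "image", "truth"])
        manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
        return manifest


def simulate_study(config: SimulationConfig) -> StudySimulation:
    """One membrane per arm for every configured series."""
    membranes = {}
    rows = []
    for arm in config.arms():
        img, truth = simulate_membrane(config, arm)
        membranes[arm] = (img, truth)
        rows.append(arm)
    manifest = pd.DataFrame(rows, columns=["series", "gender", "group"])
    return StudySimulation(config=config, membranes=membranes, manifest=manifest)


def simulate_expression_table(
    config: SimulationConfig,
    analytes: list[str] | None = None,
    n_replicates: int = 2,
) -> tuple[ExpressionMatrix, dict]:
    """Tabular shortcut: replicate-level log-normal densities, no imaging.

    Column per arm and duplicate (``s<series>_<gender>_<group>::rep<i>``);
    values are the arm's expected analyte signal times multiplicative
    log-normal technical noise (CV from the config; CV 0 reproduces the
    planted means exactly).  Statistically matches the image path's
    quantified signal in expectation.  Returns (matrix, truth dict).
    """
    if analytes is None:
        names = config.layout.analytes
        base = _baselines(config)
    else:
        names = list(analytes)
        rng0 = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBA5E]))
        draws = 2.0 ** rng0.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                                   size=len(names))
        base = dict(zip(names, draws))
        for a in config.blank_analytes:
            if a in base:
                base[a] = 0.0
    sigma_ln = _cv_sigma_ln(config.technical_cv)
    planted = config.planted()
    cols, infos = {}, []
    arm_truth = {}
    for arm in config.arms():
        series, gender, group = arm
        rng = _arm_rng(config, arm)
        scale = 2.0 ** rng.normal(0.0, config.membrane_scale_sd) if config.membrane_scale_sd else 1.0
        means = np.array([base[a] for a in names])
        for j, a in enumerate(names):
            if group == "ckd" and a in planted:
                d = _series_direction(planted[a], series, a in config.discordant_markers)
                means[j] = base[a] * (config.fold_change if d == "up" else 1.0 / config.fold_change)
        arm_truth[arm] = dict(zip(names, means))
        for i in range(n_replicates):
            noise = np.exp(rng.normal(0.0, sigma_ln, size=len(names))) if sigma_ln > 0 else 1.0
            colname = f"s{series}_{gender}_{group}::rep{i + 1}"
            cols[colname] = means * scale * noise
            infos.append({"sample_id": f"s{series}_{gender}_{group}", "series": series,
                          "gender": gender, "group": group, "replicate": i + 1})
    values = pd.DataFrame(cols, index=names)
    info = pd.DataFrame(infos, index=list(cols))
    matrix = ExpressionMatrix(values=values, sample_info=info, scale="raw")
    truth = {"baselines": base, "planted": planted, "arm_means": arm_truth}
    return matrix, truth
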