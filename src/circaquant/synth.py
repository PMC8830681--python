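"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design they are meant to exercise: round
macrophage-like cells (singlets and clumps of up to four) on a noisy
background, with amyloid uptake intensity driven by a damped ~24 h cosine;
sampling every 4 h starting 16 h post serum shock, in triplicate or
quadruplicate; heparan/chondroitin sulfate disaccharide series with
circadian structure; and a near-linear fluorescence-versus-cell-count
standard curve. Ground truth is retained alongside every output so that
the measurement and inference modules can be tested against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "HS_CODES",
    "CS_CODES",
    "GroundTruthRhythm",
    "CellSpec",
    "SceneSpec",
    "ExperimentDesign",
    "rhythm_value",
    "phase_for_zenith",
    "render_scene",
    "random_scene",
    "simulate_phagocytosis_experiment",
    "simulate_disaccharide_series",
    "simulate_pg_experiment",
    "simulate_standard_curve",
    "simulate_luminescence_trace",
]

# Sulfation-code vocabulary for the two glycosaminoglycan classes.
HS_CODES = ("0S", "2S", "NS", "6S", "2S6S", "NS2S", "NS6S", "TriS")
CS_CODES = ("0S", "2S", "4S", "6S", "2S6S", "2S4S", "4S6S", "TriS")


@dataclass(frozen=True)
class GroundTruthRhythm:
    """Parameters of a damped cosine with linear trend and additive noise.

    value(t) = equilibrium + trend_slope*(t-t0)
               + amplitude * exp(-ac_coeff*(t-t0)) * cos(2*pi*(t-t0)/period + phase)

    Units: ``period`` in hours, ``ac_coeff`` in 1/h, ``phase`` in radians;
    ``amplitude``, ``equilibrium`` and ``noise_sd`` share the measurement's
    units (intensity counts or ng/cell), ``trend_slope`` is units per hour.
    """

    amplitude: float
    ac_coeff: float
    period: float
    phase: float
    equilibrium: float
    trend_slope: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.amplitude, self.ac_coeff, self.period, self.phase,
                self.equilibrium, self.trend_slope, self.noise_sd)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("rhythm parameters must be finite")
        if self.period <= 0:
            raise ValueError(f"period must be > 0, got {self.period}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def rhythm_value(truth: GroundTruthRhythm, t, t0: float = 0.0):
    """Noiseless oscillator value at time(s) ``t`` (hours), anchored at ``t0``."""
    dt = np.asarray(t, dtype=float) - t0
    osc = truth.amplitude * np.exp(-truth.ac_coeff * dt) * np.cos(
        2.0 * np.pi * dt / truth.period + truth.phase
    )
    out = truth.equilibrium + truth.trend_slope * dt + osc
    return out if out.ndim else float(out)


def phase_for_zenith(zenith: float, t0: float, period: float) -> float:
    """Phase (radians, in [0, 2pi)) placing the undamped cosine peak at ``zenith``."""
    return float((-2.0 * np.pi * (zenith - t0) / period) % (2.0 * np.pi))


@dataclass(frozen=True)
class CellSpec:
    """One cell entry: a singlet or a chain of ``clump_size`` tangent discs."""

    x: float
    y: float
    radius: float
    intensity: float
    clump_size: int = 1

    def disc_centers(self) -> list[tuple[float, float]]:
        # Clumps extend along +x, tangent discs spaced by one diameter.
        return [(self.x + 2.0 * self.radius * k, self.y)
                for k in range(self.clump_size)]


@dataclass(frozen=True)
class SceneSpec:
    width: int
    height: int
    background: float
    noise_sd: float
    cells: tuple[CellSpec, ...] = ()
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        top = float(2 ** self.bit_depth - 1)
        if not (0 <= self.background <= top):
            raise ValueError("background outside bit-depth range")
        for c in self.cells:
            if c.radius <= 0:
                raise ValueError("cell radius must be > 0")
            if c.clump_size not in (1, 2, 3, 4):
                raise ValueError("clump_size must be in 1..4")
            if not (0 <= c.intensity <= top):
                raise ValueError("cell intensity outside bit-depth range")
            for cx, cy in c.disc_centers():
                if not (c.radius <= cx <= self.width - 1 - c.radius
                        and c.radius <= cy <= self.height - 1 - c.radius):
                    raise ValueError("cell extends outside the frame")
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        # Discs of different entries may not overlap: the scene would be
        # ambiguous against its own ground truth.
        discs = [(cx, cy, c.radius) for c in self.cells for cx, cy in c.disc_centers()]
        owner = [i for i, c in enumerate(self.cells) for _ in c.disc_centers()]
        for a in range(len(discs)):
            for b in range(a + 1, len(discs)):
                if owner[a] == owner[b]:
                    continue
                xa, ya, ra = discs[a]
                xb, yb, rb = discs[b]
                if math.hypot(xa - xb, ya - yb) < ra + rb:
                    raise ValueError(
                        f"cells {owner[a]} and {owner[b]} overlap: scene ambiguous"
                    )


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling layout of one time-course experiment (hours post shock)."""

    start: float = 16.0
    interval: float = 4.0
    span: float = 24.0
    replicates: int = 3
    cells_per_image: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.span < self.interval:
            raise ValueError("span must be >= interval")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def timepoints(self) -> np.ndarray:
        n = int(round(self.span / self.interval)) + 1
        return self.start + self.interval * np.arange(n)


def _rasterize(spec: CellSpec, height: int, width: int) -> np.ndarray:
    """Boolean mask of the union of the entry's discs (pixel-center rule)."""
    mask = np.zeros((height, width), dtype=bool)
    yy, xx = np.mgrid[0:height, 0:width]
    for cx, cy in spec.disc_centers():
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.radius ** 2
    return mask


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a scene to a float image plus its ground-truth object table.

    The image is background plane + Gaussian pixel noise, with each cell
    entry painted as a filled disc chain at its true mean intensity, then
    clipped to the bit-depth range. Identical spec (including seed) gives a
    bit-identical image.
    """
    rng = np.random.default_rng(spec.seed)
    img = np.full((spec.height, spec.width), spec.background, dtype=float)
    rows = []
    for i, cell in enumerate(spec.cells):
        mask = _rasterize(cell, spec.height, spec.width)
        img[mask] = cell.intensity
        ys, xs = np.nonzero(mask)
        rows.append({
            "object_id": i,
            "area_px2": int(mask.sum()),
            "true_mean": cell.intensity,
            "clump_size": cell.clump_size,
            "x": float(xs.mean()),
            "y": float(ys.mean()),
        })
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    np.clip(img, 0.0, float(2 ** spec.bit_depth - 1), out=img)
    truth = pd.DataFrame(
        rows, columns=["object_id", "area_px2", "true_mean", "clump_size", "x", "y"]
    )
    return img, truth


def _place_cells(
    rng: np.random.Generator,
    n_cells: int,
    width: int,
    height: int,
    radius: float,
    min_gap: float,
    clump_probs: tuple[float, ...],
) -> list[tuple[float, float, int]]:
    """Rejection-sample non-overlapping (x, y, clump_size) placements."""
    placed: list[tuple[float, float, int]] = []
    attempts = 0
    while len(placed) < n_cells and attempts < 20000:
        attempts += 1
        k = int(rng.choice(len(clump_probs), p=clump_probs)) + 1
        margin = radius + 1.0
        x = rng.uniform(margin, width - 1 - margin - 2.0 * radius * (k - 1))
        y = rng.uniform(margin, height - 1 - margin)
        new = [(x + 2.0 * radius * j, y) for j in range(k)]
        ok = True
        for px, py, pk in placed:
            for ox, oy in [(px + 2.0 * radius * j, py) for j in range(pk)]:
                for nx, ny in new:
                    if math.hypot(nx - ox, ny - oy) < 2.0 * radius + min_gap:
                        ok = False
        if ok:
            placed.append((x, y, k))
    if len(placed) < n_cells:
        raise RuntimeError("could not place requested cells without overlap")
    return placed


@dataclass
class PhagocytosisSample:
    """One simulated image with its acquisition coordinates and truth table."""

    time_ps: float
    replicate: int
    image: np.ndarray
    truth: pd.DataFrame


def simulate_phagocytosis_experiment(
    design: ExperimentDesign,
    truth: GroundTruthRhythm,
    *,
    width: int = 384,
    height: int = 384,
    radius: float = 10.0,
    background: float = 100.0,
    noise_sd: float = 4.0,
    dispersion: float = 0.10,
    clump_probs: tuple[float, ...] = (0.7, 0.15, 0.1, 0.05),
    min_gap: float = 6.0,
) -> list[PhagocytosisSample]:
    """Simulate the fluorescence time-course: one scene per (timepoint, replicate).

    Each scene's cells carry true mean intensity max(0, rhythm_value(t))
    perturbed per cell by multiplicative lognormal dispersion (median
    preserved), emulating cell-to-cell variability in uptake.
    """
    t0 = design.start
    root = np.random.default_rng(design.seed)
    samples: list[PhagocytosisSample] = []
    for t in design.timepoints():
        level = max(0.0, rhythm_value(truth, t, t0))
        for rep in range(1, design.replicates + 1):
            seed = int(root.integers(0, 2**31 - 1))
            rng = np.random.default_rng(seed)
            placements = _place_cells(
                rng, design.cells_per_image, width, height, radius, min_gap, clump_probs
            )
            cells = []
            for x, y, k in placements:
                factor = float(np.exp(rng.normal(0.0, dispersion))) if dispersion > 0 else 1.0
                noisy_level = level + rng.normal(0.0, truth.noise_sd) if truth.noise_sd else level
                intensity = max(0.0, noisy_level * factor)
                intensity = min(intensity, float(2**16 - 1))
                cells.append(CellSpec(x=x, y=y, radius=radius,
                                      intensity=intensity, clump_size=k))
            spec = SceneSpec(width=width, height=height, background=background,
                             noise_sd=noise_sd, cells=tuple(cells), seed=seed)
            img, truth_table = render_scene(spec)
            truth_table.insert(0, "replicate", rep)
            truth_table.insert(0, "time_ps", t)
            samples.append(PhagocytosisSample(float(t), rep, img, truth_table))
    return samples


def random_scene(
    seed: int,
    n_cells: int = 12,
    *,
    width: int = 384,
    height: int = 384,
    radius: float = 10.0,
    background: float = 100.0,
    noise_sd: float = 4.0,
    intensity: float = 2000.0,
    dispersion: float = 0.10,
    clump_probs: tuple[float, ...] = (0.7, 0.15, 0.1, 0.05),
    min_gap: float = 6.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """One randomly-placed scene with its ground-truth table.

    Cell intensities scatter lognormally (median ``intensity``); defaults
    give contrast far above the noise floor and inter-object gaps of at
    least ``min_gap`` pixels.
    """
    rng = np.random.default_rng(seed)
    placements = _place_cells(rng, n_cells, width, height, radius,
                              min_gap, clump_probs)
    cells = []
    for x, y, k in placements:
        factor = float(np.exp(rng.normal(0.0, dispersion))) if dispersion > 0 else 1.0
        cells.append(CellSpec(x=x, y=y, radius=radius,
                              intensity=min(intensity * factor, float(2**16 - 1)),
                              clump_size=k))
    spec = SceneSpec(width=width, height=height, background=background,
                     noise_sd=noise_sd, cells=tuple(cells), seed=seed)
    return render_scene(spec)


def _validate_code(gag_class: str, code: str) -> None:
    vocab = {"HS": HS_CODES, "CS": CS_CODES}
    if gag_class not in vocab:
        raise ValueError(f"unknown glycosaminoglycan class {gag_class!r}")
    if code not in vocab[gag_class]:
        raise ValueError(f"unknown sulfation code {code!r} for class {gag_class}")


def simulate_disaccharide_series(
    species: dict[tuple[str, str], GroundTruthRhythm],
    design: ExperimentDesign,
    *,
    compartment: str = "cell",
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-species disaccharide concentrations with circadian structure.

    ``species`` maps (class, sulfation code) — e.g. ("HS", "NS2S") — to its
    rhythm truth. Negative draws are clamped to 0 and flagged in the
    ``truncated`` column.
    """
    for gag_class, code in species:
        _validate_code(gag_class, code)
    rng = np.random.default_rng(design.seed if seed is None else seed)
    t0 = design.start
    rows = []
    for (gag_class, code), truth in species.items():
        for t in design.timepoints():
            base = rhythm_value(truth, t, t0)
            for rep in range(1, design.replicates + 1):
                v = base + (rng.normal(0.0, truth.noise_sd) if truth.noise_sd else 0.0)
                truncated = v < 0
                rows.append({
                    "class": gag_class,
                    "code": code,
                    "compartment": compartment,
                    "time_ps": float(t),
                    "replicate": rep,
                    "value": max(0.0, float(v)),
                    "truncated": bool(truncated),
                })
    return pd.DataFrame(rows)


def simulate_pg_experiment(
    species: dict[tuple[str, str], GroundTruthRhythm],
    design: ExperimentDesign,
    *,
    cells_per_sample: float = 1.0e6,
    cell_count_cv: float = 0.05,
    curve_slope: float = 2.0e-3,
    curve_intercept: float = 150.0,
    dilution: float = 5.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Raw proteoglycan table as the mass-spec + CyQUANT workflow sees it.

    Per-cell truth rhythms (ng/cell) are scaled by a per-sample cell count;
    the table carries the raw nanogram amount plus the CyQUANT fluorescence
    of the diluted cell aliquot, so downstream normalization must recover
    the per-cell values through the standard curve.
    """
    percell = simulate_disaccharide_series(species, design, compartment="cell",
                                           seed=seed)
    rng = np.random.default_rng((design.seed if seed is None else seed) + 1)
    counts = {}
    for key in percell.groupby(["time_ps", "replicate"]).groups:
        n = cells_per_sample * float(np.exp(rng.normal(0.0, cell_count_cv)))
        counts[key] = n
    percell["true_cell_count"] = [
        counts[(t, r)] for t, r in zip(percell["time_ps"], percell["replicate"])
    ]
    percell["raw_ng"] = percell["value"] * percell["true_cell_count"]
    # Fluorescence read on a 1/dilution aliquot of the lysed sample.
    percell["cyquant_fluorescence"] = (
        curve_slope * percell["true_cell_count"] / dilution + curve_intercept
    )
    percell["dilution"] = dilution
    return percell.rename(columns={"value": "true_ng_per_cell"})


def simulate_standard_curve(
    slope: float,
    intercept: float,
    counts,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fluorescence-versus-known-cell-count calibration table."""
    if slope == 0:
        raise ValueError("slope must be nonzero")
    counts = np.asarray(counts, dtype=float)
    rng = np.random.default_rng(seed)
    fluor = slope * counts + intercept
    if noise_sd > 0:
        fluor = fluor + rng.normal(0.0, noise_sd, size=counts.shape)
    return pd.DataFrame({"cell_count": counts, "fluorescence": fluor})


def simulate_luminescence_trace(
    truth: GroundTruthRhythm,
    design: ExperimentDesign,
    *,
    step: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Dense bioluminescence-reporter-style trace for phase anchoring."""
    if step <= 0 or step > 0.5:
        raise ValueError("step must be in (0, 0.5] h")
    t = np.arange(design.start, design.start + design.span + 1e-9, step)
    values = rhythm_value(truth, t, design.start)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(design.seed if seed is None else seed)
        values = values + rng.normal(0.0, truth.noise_sd, size=t.shape)
    return pd.DataFrame({"time_ps": t, "replicate": 1, "value": values})
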