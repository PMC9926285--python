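"""Seeded generators for microscopy-like images and single-cell traces.

These generators make every analysis stage testable without experimental
data.  Two kinds of fixtures are produced:

* **Images** of single cells with a conserved total fluorophore budget
  ``F`` of which a fraction ``f`` is concentrated in a small nuclear
  region.  The cytosolic pool is projected over the whole cell footprint
  (in a widefield image the cytoplasm above and below the nucleus also
  contributes along the optical axis), so the expected intensity is

      background                     outside the cell,
      b + (1 - f) * F / area_cell    in the cell body, plus
      f * F / area_nucleus           inside the nucleus.

  At ``f = 0`` the cell is uniform; the expected within-cell photon sum is
  ``F`` regardless of ``f`` — redistribution, not production.  Realized
  pixels add Poisson shot noise and Gaussian read noise (the standard
  camera model), clipped at zero.

* **Trace populations** mixing off/plateau/on states with lognormal
  per-state intensity components, unimodal within a state and bimodal in
  transition regions.

Randomness: one global seed expands into per-cell/per-frame substreams via
``np.random.default_rng([seed, index])``, so any subset of a dataset is
reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .regulon import (
    RegulonParams,
    _check_dt,
    _classify_window,
    _lognormal_et,
    _run_point,
    _zero_state,
)

__all__ = [
    "ImageSpec",
    "PopulationSpec",
    "CapacityError",
    "make_cell_image",
    "make_field",
    "make_trace_population",
    "make_regulon_dataset",
    "expected_image",
]


class CapacityError(RuntimeError):
    """Rejection sampling could not place all requested cells."""


@dataclass(frozen=True)
class ImageSpec:
    """Geometry, photon budget and noise of one synthetic cell image.

    The cell is an axis-aligned ellipse, the nucleus a disk contained in
    it.  ``total_intensity`` is the expected photon sum over the cell
    (above background), ``nuclear_fraction`` the share concentrated in the
    nucleus.
    """

    shape: tuple[int, int] = (96, 96)
    cell_center: tuple[float, float] = (48.0, 48.0)  # (row, col)
    cell_axes: tuple[float, float] = (28.0, 22.0)  # semi-axes (row, col)
    nucleus_center: tuple[float, float] = (48.0, 48.0)
    nucleus_radius: float = 8.0
    total_intensity: float = 2e4
    nuclear_fraction: float = 0.0
    background: float = 100.0
    read_noise: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.nuclear_fraction <= 1:
            raise ValueError("nuclear_fraction must lie in [0, 1]")
        if self.background < 0 or self.read_noise < 0 or self.total_intensity <= 0:
            raise ValueError("intensity parameters must be >= 0 (budget > 0)")
        if min(self.cell_axes) <= 0 or self.nucleus_radius <= 0:
            raise ValueError("geometry lengths must be > 0")


def _region_masks(spec: ImageSpec):
    rows, cols = np.indices(spec.shape)
    cr, cc = spec.cell_center
    ar, ac = spec.cell_axes
    cell = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0
    nr, nc = spec.nucleus_center
    nucleus = (rows - nr) ** 2 + (cols - nc) ** 2 <= spec.nucleus_radius**2
    if not np.all(cell[nucleus]):
        raise ValueError("nucleus must be contained in the cell")
    if not cell.any():
        raise ValueError("cell footprint is empty")
    return cell, nucleus


def expected_image(spec: ImageSpec) -> np.ndarray:
    """Noise-free expected intensity raster for a spec."""
    cell, nucleus = _region_masks(spec)
    f, F = spec.nuclear_fraction, spec.total_intensity
    expected = np.full(spec.shape, spec.background, dtype=float)
    expected[cell] += (1.0 - f) * F / cell.sum()
    expected[nucleus] += f * F / nucleus.sum()
    return expected


def _realize(expected: np.ndarray, sigma: float, rng: np.random.Generator):
    img = rng.poisson(expected).astype(float)
    if sigma > 0:
        img += rng.normal(0.0, sigma, expected.shape)
    return np.clip(img, 0.0, None)


def make_cell_image(spec: ImageSpec):
    """Render one cell; returns ``(frame, cell_mask, nuclear_fraction)``.

    The frame carries the ground-truth cell mask so the scoring pipeline
    can restrict itself to cell pixels; callers wanting the maskless
    (Otsu) path can drop it.  Deterministic under a fixed seed.
    """
    from .localization import ImageFrame

    cell, _ = _region_masks(spec)
    rng = np.random.default_rng(spec.seed)
    pixels = _realize(expected_image(spec), spec.read_noise, rng)
    return ImageFrame(pixels, mask=cell.copy()), cell, spec.nuclear_fraction


def make_field(
    n_cells: int,
    f_values,
    base_spec: ImageSpec,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    max_tries: int = 10_000,
):
    """Multi-cell frame with per-cell ground truth.

    Cells share the geometry of ``base_spec`` and are placed uniformly at
    random without overlap (bounding-circle rejection sampling; a
    :class:`CapacityError` is raised after ``max_tries`` failed
    placements).  Returns ``(frame, label_mask, table)`` where the label
    mask holds 1-based cell ids (0 = background) and the table lists each
    cell's center and nuclear fraction.
    """
    from .localization import ImageFrame

    f_values = list(f_values)
    if len(f_values) != n_cells:
        raise ValueError("need one nuclear fraction per cell")
    radius = max(base_spec.cell_axes)
    placement_rng = np.random.default_rng([seed, 0])
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n_cells:
        if tries >= max_tries:
            raise CapacityError(
                f"placed only {len(centers)}/{n_cells} cells in {max_tries} tries"
            )
        tries += 1
        r = placement_rng.uniform(radius + 1, shape[0] - radius - 1)
        c = placement_rng.uniform(radius + 1, shape[1] - radius - 1)
        if all((r - r0) ** 2 + (c - c0) ** 2 > (2 * radius + 2) ** 2 for r0, c0 in centers):
            centers.append((r, c))

    expected = np.full(shape, base_spec.background, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    for idx, ((r, c), f) in enumerate(zip(centers, f_values), start=1):
        spec = replace(
            base_spec,
            shape=shape,
            cell_center=(r, c),
            nucleus_center=(r, c),
            nuclear_fraction=float(f),
            background=0.0,
        )
        expected += expected_image(spec)
        cell, _ = _region_masks(spec)
        labels[cell] = idx
        rows.append({"cell_id": idx, "row": r, "col": c, "nuclear_fraction": float(f)})

    noise_rng = np.random.default_rng([seed, n_cells + 1])
    pixels = _realize(expected, base_spec.read_noise, noise_rng)
    frame = ImageFrame(pixels, mask=labels > 0)
    return frame, labels, pd.DataFrame(rows)


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture model for single-cell reporter trace populations.

    Each cell draws a state from the ``(off, plateau, on)`` mixture and
    then, per timepoint, an intensity from the lognormal component of that
    state.  The default component medians (1, 30, 300) are separated far
    beyond the default log-sd of 0.4, so any two-state mixture is clearly
    bimodal.
    """

    n_cells: int = 1000
    weights: tuple[float, float, float] = (0.7, 0.3, 0.0)
    log_means: tuple[float, float, float] = (0.0, np.log(30.0), np.log(300.0))
    log_sds: tuple[float, float, float] = (0.4, 0.4, 0.4)
    timepoints: tuple[float, ...] = (0.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be >= 0 and sum to 1")
        if any(sd <= 0 for sd in self.log_sds):
            raise ValueError("log-sds must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


_STATE_NAMES = ("off", "plateau", "on")


def make_trace_population(spec: PopulationSpec) -> pd.DataFrame:
    """Per-cell, per-timepoint reporter intensities from the state mixture.

    Returns a table with columns ``cell_id``, ``time``, ``intensity`` and
    the ground-truth ``state``.
    """
    state_rng = np.random.default_rng([spec.seed, 0])
    states = state_rng.choice(3, size=spec.n_cells, p=np.asarray(spec.weights))
    rows = []
    for cell in range(spec.n_cells):
        cell_rng = np.random.default_rng([spec.seed, cell + 1])
        st = states[cell]
        draws = np.exp(
            cell_rng.normal(spec.log_means[st], spec.log_sds[st], len(spec.timepoints))
        )
        for t, value in zip(spec.timepoints, draws):
            rows.append(
                {
                    "cell_id": cell,
                    "time": t,
                    "intensity": float(value),
                    "state": _STATE_NAMES[st],
                }
            )
    return pd.DataFrame(rows)


def make_regulon_dataset(
    p: RegulonParams,
    s_out_grid,
    cv_etL: float = 0.3,
    n_cells: int = 200,
    seed: int = 0,
    noise_cv: float = 0.1,
    dt: float | None = None,
) -> pd.DataFrame:
    """Simulated reporter readouts over an external-phosphate grid.

    Runs the population downward sweep cell by cell (per-cell low-affinity
    capacity drawn as in the regulon module) and emits the tail-window
    reporter levels with multiplicative lognormal measurement noise of
    coefficient of variation ``noise_cv``, keyed by ``s_out`` and cell,
    together with the ground-truth state label (``MIXED`` marks cells the
    classifier could not assign).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    dt = _check_dt(p, dt)
    rng = np.random.default_rng([seed, 0])
    et_L = _lognormal_et(rng, p.params_L.et, cv_etL, n_cells)
    noise_rng = np.random.default_rng([seed, 1])
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    state = _zero_state(n_cells)
    duration, window = 12.0 / p.delta, 1.0 / p.delta
    rows = []
    for s_out in sorted(float(s) for s in s_out_grid)[::-1]:
        state, means, first, last = _run_point(state, s_out, et_L, p, dt, duration, window)
        labels, ok = _classify_window(means, first, last, p, strict=False)
        for cell in range(n_cells):
            label = labels[cell]
            name = "MIXED" if (label is None or not ok[cell]) else label.value
            noisy = {
                key: float(
                    means[key][cell]
                    * (np.exp(noise_rng.normal(-0.5 * sigma**2, sigma)) if sigma else 1.0)
                )
                for key in ("p_plateau", "p_decoupled")
            }
            rows.append(
                {
                    "s_out": s_out,
                    "cell_id": cell,
                    "p_plateau": noisy["p_plateau"],
                    "p_decoupled": noisy["p_decoupled"],
                    "label": name,
                }
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["s_out", "cell_id"], kind="stable").reset_index(drop=True)
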