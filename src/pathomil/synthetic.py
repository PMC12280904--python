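"""Synthetic study generator: textured tiles, composite slides, likelihood
bags, and survival cohorts with known ground truth.

The generator emulates the statistical structure the pipeline assumes:

* each patient carries a standard-normal latent risk ``r``;
* the slide's patch likelihoods are i.i.d. ``Beta(a(r), b(r))`` with a
  link that makes the mean strictly increasing in ``r``;
* survival time is exponential with hazard ``baseline * exp(beta * r)``,
  censored by an independent Uniform(0, censor_max) follow-up;
* tiles are class-conditional textures (tumor / stroma / mucosa /
  adipose / background) in hematoxylin-and-eosin-like colors, so stain
  normalization, masking and patch classification all have signal to find.

Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import disk

from .core import RGBPatch, SlideLikelihoods

__all__ = [
    "TextureClassSpec",
    "SimCohortParams",
    "DEFAULT_SPECS",
    "make_patch",
    "make_wsi",
    "simulate_slide_likelihoods",
    "simulate_cohort",
    "make_sparse_cox_cohort",
    "simulate_mini_study",
]


@dataclass(frozen=True)
class TextureClassSpec:
    """Texture recipe of one tissue class."""

    name: str
    base_color: tuple[int, int, int]
    nucleus_density: float = 0.0       # expected nuclei per 512x512 tile
    nucleus_radius: tuple[int, int] = (4, 9)
    nucleus_color: tuple[int, int, int] = (70, 40, 110)
    fiber_strength: float = 0.0        # 0..1 amplitude of oriented stripes
    fiber_angle: float = 0.6           # radians
    adipocyte_density: float = 0.0     # expected adipocytes per 512x512 tile
    adipocyte_radius: tuple[int, int] = (18, 40)
    noise_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.nucleus_density < 0 or self.adipocyte_density < 0:
            raise ValueError("densities must be >= 0")
        if any(not 0 <= v <= 255 for v in self.base_color):
            raise ValueError("colors must lie in [0, 255]")


DEFAULT_SPECS: dict[str, TextureClassSpec] = {
    "tumor": TextureClassSpec("tumor", base_color=(185, 120, 175), nucleus_density=220.0,
                              nucleus_radius=(4, 9)),
    "stroma": TextureClassSpec("stroma", base_color=(228, 140, 178), nucleus_density=35.0,
                               fiber_strength=0.35),
    "mucosa": TextureClassSpec("mucosa", base_color=(210, 140, 185), nucleus_density=90.0,
                               nucleus_radius=(3, 6)),
    "adipose": TextureClassSpec("adipose", base_color=(246, 235, 242), adipocyte_density=28.0,
                                noise_sd=3.0),
    "background": TextureClassSpec("background", base_color=(252, 252, 252), noise_sd=1.5),
}


def make_patch(spec: TextureClassSpec, seed: int, size: int = 512,
               slide_id: str = "synthetic", grid_row: int = 0, grid_col: int = 0) -> RGBPatch:
    """Render one class-conditional texture tile; deterministic per seed."""
    rng = np.random.default_rng(seed)
    img = np.empty((size, size, 3), dtype=float)
    img[:] = spec.base_color
    if spec.fiber_strength > 0:
        yy, xx = np.mgrid[0:size, 0:size]
        phase = np.cos(spec.fiber_angle) * xx + np.sin(spec.fiber_angle) * yy
        stripes = np.sin(2 * np.pi * phase / 24.0 + rng.uniform(0, 2 * np.pi))
        img += (spec.fiber_strength * 25.0 * stripes)[:, :, None]
    scale = (size / 512.0) ** 2
    n_adipo = rng.poisson(spec.adipocyte_density * scale)
    for _ in range(n_adipo):
        r = rng.integers(*spec.adipocyte_radius)
        cy, cx = rng.integers(0, size, size=2)
        rr, cc = disk((cy, cx), r, shape=(size, size))
        img[rr, cc] = (252, 250, 252)
    n_nuc = rng.poisson(spec.nucleus_density * scale)
    for _ in range(n_nuc):
        r = rng.integers(*spec.nucleus_radius)
        cy, cx = rng.integers(0, size, size=2)
        rr, cc = disk((cy, cx), max(int(r * size / 512.0), 1), shape=(size, size))
        img[rr, cc] = spec.nucleus_color
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.rint(img).clip(0, 255).astype(np.uint8)
    return RGBPatch(slide_id=slide_id, grid_row=grid_row, grid_col=grid_col,
                    origin_xy=(grid_col * size, grid_row * size), pixels=pixels)


def make_wsi(layout: list[list[str]], specs: dict[str, TextureClassSpec] | None = None,
             seed: int = 0, tile_size: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Mosaic a grid of class tiles into one slide image.

    Returns the image and a (rows, cols) array of true class labels.
    """
    specs = specs or DEFAULT_SPECS
    lay = np.asarray(layout, dtype=object)
    if lay.size == 0:
        raise ValueError("layout must be non-empty")
    rows, cols = lay.shape
    image = np.empty((rows * tile_size, cols * tile_size, 3), dtype=np.uint8)
    for r in range(rows):
        for c in range(cols):
            cls = str(lay[r, c])
            if cls not in specs:
                raise KeyError(f"unknown class label: {cls!r}")
            tile = make_patch(specs[cls], seed=seed * 1_000_003 + r * 1009 + c,
                              size=tile_size, grid_row=r, grid_col=c)
            image[r * tile_size : (r + 1) * tile_size,
                  c * tile_size : (c + 1) * tile_size] = tile.pixels
    return image, lay


@dataclass(frozen=True)
class SimCohortParams:
    """Cohort-simulation parameters.

    Defaults mirror a realistic colorectal-cancer study at desk scale:
    hazard ``baseline_hazard * exp(beta * r)`` per month gives ~5-year
    survival around 70-80% for average risk, with uniform administrative
    censoring over 10 years of accrual.
    """

    n_patients: int = 200
    beta: float = 1.0
    baseline_hazard: float = 0.004     # events per month at r = 0
    censor_max: float = 120.0          # months
    patches_per_slide: int = 100
    link_scale: float = 0.8            # a(r) = exp(link_scale * r), clipped
    link_clip: tuple[float, float] = (0.2, 20.0)
    treatment_frac: float = 0.0        # fraction randomized to adjuvant chemo
    chemo_log_hr: float = 0.0          # main chemo effect on log-hazard
    chemo_interaction_log_hr: float = 0.0  # extra chemo effect when r > 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.patches_per_slide < 1:
            raise ValueError("patches_per_slide must be >= 1")
        if self.link_clip[0] <= 0:
            raise ValueError("Beta parameters must stay positive")


def _beta_link(r: float, params: SimCohortParams) -> tuple[float, float]:
    lo, hi = params.link_clip
    a = float(np.clip(np.exp(params.link_scale * r), lo, hi))
    b = float(np.clip(np.exp(-params.link_scale * r), lo, hi))
    return a, b


def simulate_slide_likelihoods(r: float, params: SimCohortParams,
                               rng: np.random.Generator | None = None,
                               slide_id: str = "sim") -> SlideLikelihoods:
    """Draw one slide's likelihood bag: i.i.d. Beta(a(r), b(r)) patches."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    a, b = _beta_link(r, params)
    probs = rng.beta(a, b, size=params.patches_per_slide)
    return SlideLikelihoods(slide_id=slide_id, probabilities=probs,
                            predicted_labels=(probs > 0.5).astype(int))


def simulate_cohort(params: SimCohortParams
                    ) -> tuple[list[SlideLikelihoods], pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: bags, observed survival, and ground truth.

    Returns ``(bags, cohort, truth)`` where ``cohort`` has columns
    slide_id / time / event (/ treatment) and ``truth`` records each
    patient's latent risk, uncensored event time, and true 5-year label.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    r = rng.standard_normal(n)
    treat = (rng.random(n) < params.treatment_frac).astype(int)
    log_hr = params.beta * r + params.chemo_log_hr * treat \
        + params.chemo_interaction_log_hr * treat * (r > 0)
    hazard = params.baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, params.censor_max, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    ids = [f"slide_{i:04d}" for i in range(n)]
    bags = [simulate_slide_likelihoods(r[i], params, rng, slide_id=ids[i]) for i in range(n)]
    cohort = pd.DataFrame({"slide_id": ids, "time": time, "event": event,
                           "treatment": treat})
    truth = pd.DataFrame({"slide_id": ids, "latent_risk": r, "event_time": t_event,
                          "five_year_label": (t_event <= 60.0).astype(int)})
    return bags, cohort, truth


def make_sparse_cox_cohort(n: int, p: int, informative: list[int], beta: float,
                           baseline_hazard: float = 0.01, censor_max: float = 120.0,
                           seed: int = 0) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian feature matrix with a sparse true Cox model.

    Returns ``(X, time, event, true_risk)``; columns listed in
    ``informative`` carry coefficient ``beta``, all others zero.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    coefs = np.zeros(p)
    coefs[list(informative)] = beta
    true_risk = X @ coefs
    t_event = rng.exponential(1.0 / (baseline_hazard * np.exp(true_risk)))
    t_cens = rng.uniform(0, censor_max, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    cols = [f"feat_{j:03d}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), time, event, true_risk


def simulate_mini_study(out_dir, n_slides: int = 40, grid: int = 4,
                        tile_size: int = 64, params: SimCohortParams | None = None,
                        seed: int = 0):
    """Write a complete miniature imaging study to ``out_dir``.

    Each slide is a mosaic whose tumor-tile fraction follows
    ``sigmoid(1.5 * r)`` of the patient's latent risk, so patch textures
    carry the survival signal end to end. Produces ``slides/<id>.png``,
    ``cohort.csv`` and ``truth.csv``.
    """
    from pathlib import Path

    from PIL import Image

    params = params or SimCohortParams(n_patients=n_slides, seed=seed)
    params = replace(params, n_patients=n_slides, seed=seed)
    rng = np.random.default_rng(seed)
    _, cohort, truth = simulate_cohort(params)
    out = Path(out_dir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    tumor_frac = 1.0 / (1.0 + np.exp(-1.5 * truth["latent_risk"].to_numpy()))
    for i, sid in enumerate(cohort["slide_id"]):
        cell_rng = np.random.default_rng([seed, i])
        layout = np.where(cell_rng.random((grid, grid)) < tumor_frac[i],
                          "tumor", "stroma").astype(object)
        # one background tile so masking always has something to discard
        layout[0, 0] = "background"
        image, _ = make_wsi(layout.tolist(), seed=seed * 7919 + i, tile_size=tile_size)
        Image.fromarray(image).save(out / "slides" / f"{sid}.png")
    cohort.to_csv(out / "cohort.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    return out
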