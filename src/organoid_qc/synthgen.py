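"""Synthetic brain-organoid cohorts with known ground truth.

The generator emulates a 12-line x 6-organoid day-30 cohort containing two
latent quality classes.  High-quality organoids are compact near-spheres
with small peripheral neuroepithelial buds; low-quality organoids are
larger, irregular and carry bright fluid-filled cysts.  Mesenchymal-cell
(MC) abundance is coupled to organoid size through a logit-linear link in
the Feret diameter, so larger (low-quality) organoids carry more MC — the
association the morphology-based quality screen is meant to detect.

Everything is driven by a single integer seed: identical configuration
gives a byte-identical cohort, including rendered images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import polygon as draw_polygon
from skimage.draw import disk as draw_disk

from .errors import ConfigurationError, DomainError, RenderError
from .morphometry import max_feret_distance

__all__ = [
    "CohortConfig",
    "SyntheticOrganoid",
    "CELL_TYPES",
    "generate_cohort",
    "render_organoid_image",
    "generate_expression_mixture",
    "generate_fluorescence_panel",
    "make_signature",
    "cohort_truth_table",
    "write_cohort",
    "load_config_file",
]

CELL_TYPES = [
    "mesenchymal",
    "radial_glia",
    "neural_progenitor",
    "neuron_excitatory",
    "neuron_inhibitory",
    "intermediate_progenitor",
    "astrocyte",
    "oligodendrocyte_precursor",
    "choroid_plexus",
    "neural_crest",
]

# per-line probability of producing a High-quality organoid; strong
# line-to-line spread (quality is largely a property of the hPSC line),
# averaging ~0.72 so a 72-organoid cohort lands near 54 High / 18 Low
DEFAULT_LINE_HIGH_PROBS = (0.95, 0.9, 0.9, 0.85, 0.85, 0.8, 0.8, 0.75, 0.6, 0.5, 0.4, 0.3)


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    Feret distributions are lognormal, parameterized by the class median in
    um and the SD on the log scale; cyst counts are Poisson.  The MC
    fraction follows inverse-logit(intercept + slope * feret + noise).
    """

    n_lines: int = 12
    organoids_per_line: int = 6
    high_quality_prob_per_line: tuple = DEFAULT_LINE_HIGH_PROBS
    feret_um_dist_high: tuple = (2400.0, 0.15)  # (median um, log-SD)
    feret_um_dist_low: tuple = (3800.0, 0.15)
    cyst_count_dist_high: float = 0.2  # Poisson mean
    cyst_count_dist_low: float = 3.0
    mc_fraction_intercept: float = -7.29  # logit scale
    mc_fraction_slope: float = 1.81e-3  # per um of Feret, logit scale
    mc_noise_sd: float = 1.6  # logit scale
    pixel_size_um: float = 12.0
    image_shape: tuple = (640, 640)
    expression_noise_cv: float = 0.1
    n_genes: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines <= 0 or self.organoids_per_line <= 0:
            raise ConfigurationError("n_lines and organoids_per_line must be positive")
        probs = np.asarray(self.high_quality_prob_per_line, dtype=float)
        if len(probs) != self.n_lines:
            raise ConfigurationError(
                f"need {self.n_lines} per-line probabilities, got {len(probs)}"
            )
        if ((probs < 0) | (probs > 1)).any():
            raise ConfigurationError("probabilities must be in [0, 1]")
        for name in ("feret_um_dist_high", "feret_um_dist_low"):
            med, sd = getattr(self, name)
            if med <= 0 or sd <= 0:
                raise ConfigurationError(f"{name} parameters must be strictly positive")
        if self.cyst_count_dist_high < 0 or self.cyst_count_dist_low < 0:
            raise ConfigurationError("Poisson means must be non-negative")
        if self.mc_noise_sd < 0 or self.expression_noise_cv < 0:
            raise ConfigurationError("noise scales must be non-negative")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.n_genes < len(CELL_TYPES):
            raise ConfigurationError("n_genes must be at least the number of cell types")


@dataclass
class SyntheticOrganoid:
    """One generated organoid with its full ground truth."""

    organoid_id: str
    line_id: str
    true_quality: str  # "High" | "Low"
    true_features: dict  # MorphometryRecord-compatible feature values
    true_fractions: np.ndarray  # simplex over CELL_TYPES
    fluorescence_truth: dict = field(default_factory=dict)
    render_seed: int = 0
    image: np.ndarray | None = None
    cyst_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Cohort generation


def _draw_features(rng: np.random.Generator, quality: str, cfg: CohortConfig) -> dict:
    """Class-conditional nine-parameter feature vector.

    Size and cyst burden separate the classes strongly; pure shape
    descriptors overlap heavily (they discriminate weakly in real day-30
    cohorts, where experts key on size, cysts and outline).
    """
    high = quality == "High"
    med, logsd = cfg.feret_um_dist_high if high else cfg.feret_um_dist_low
    feret = float(rng.lognormal(np.log(med), logsd))
    aspect = 1.0 + float(rng.gamma(2.0, 0.06 if high else 0.08))
    # ellipse with major axis = feret, mildly eroded fill factor
    fill = float(rng.uniform(0.85, 0.99))
    area = np.pi / 4.0 * feret * (feret / aspect) * fill
    circ = float(np.clip(rng.normal(0.79 if high else 0.745, 0.085), 0.35, 1.0))
    perim = float(np.sqrt(4.0 * np.pi * area / circ))
    roundness = min(1.0, 4.0 * area / (np.pi * feret**2))
    solidity = float(np.clip(rng.normal(0.945 if high else 0.925, 0.035), 0.6, 1.0))
    lam = cfg.cyst_count_dist_high if high else cfg.cyst_count_dist_low
    cysts = int(rng.poisson(lam))
    cyst_ratio = 0.0 if cysts == 0 else float(np.clip(rng.beta(2.0, 12.0) + 0.02 * cysts, 0, 0.6))
    return {
        "area_um2": area,
        "perimeter_um": perim,
        "feret_um": feret,
        "aspect_ratio": aspect,
        "circularity": circ,
        "roundness": roundness,
        "solidity": solidity,
        "cysts_count": cysts,
        "cysts_area_ratio": cyst_ratio,
    }


def _inv_logit(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: CohortConfig) -> list[SyntheticOrganoid]:
    """Generate the full cohort (no images; see :func:`render_organoid_image`).

    Per organoid: a quality class drawn from the line's High probability,
    a class-conditional feature vector, and a cell-type fraction simplex
    whose mesenchymal component follows the logit-linear link in Feret.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    render_seeds = np.random.SeedSequence(config.seed).spawn(
        config.n_lines * config.organoids_per_line
    )
    cohort: list[SyntheticOrganoid] = []
    idx = 0
    for li in range(config.n_lines):
        line_id = f"line_{li + 1:02d}"
        p_high = float(np.asarray(config.high_quality_prob_per_line, dtype=float)[li])
        for oj in range(config.organoids_per_line):
            quality = "High" if rng.uniform() < p_high else "Low"
            feats = _draw_features(rng, quality, config)
            logit_mc = (
                config.mc_fraction_intercept
                + config.mc_fraction_slope * feats["feret_um"]
                + rng.normal(0.0, config.mc_noise_sd)
            )
            mc = _inv_logit(logit_mc)
            rest = rng.dirichlet(np.full(len(CELL_TYPES) - 1, 2.0)) * (1.0 - mc)
            fractions = np.concatenate([[mc], rest])
            cohort.append(
                SyntheticOrganoid(
                    organoid_id=f"{line_id}_org_{oj + 1}",
                    line_id=line_id,
                    true_quality=quality,
                    true_features=feats,
                    true_fractions=fractions,
                    render_seed=int(render_seeds[idx].generate_state(1)[0] % (2**31)),
                )
            )
            idx += 1
    return cohort


def cohort_truth_table(cohort: list[SyntheticOrganoid]) -> pd.DataFrame:
    """Flatten a cohort into the feature-table layout the pipeline consumes."""
    rows = []
    for org in cohort:
        row = {
            "organoid_id": org.organoid_id,
            "line_id": org.line_id,
            "expert_label": org.true_quality,
            **org.true_features,
        }
        for ct, fr in zip(CELL_TYPES, org.true_fractions):
            row[f"frac_{ct}"] = fr
        row.update(org.fluorescence_truth)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Image rendering


def _shape_polygon(rng: np.random.Generator, quality: str, aspect: float) -> np.ndarray:
    """Unit-scale outline polygon (n x 2) of one organoid."""
    theta = np.linspace(0.0, 2.0 * np.pi, 720, endpoint=False)
    a, b = 1.0, 1.0 / aspect
    phi = rng.uniform(0, 2 * np.pi)
    r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    if quality == "High":
        # small peripheral buds
        for _ in range(int(rng.integers(3, 7))):
            c = rng.uniform(0, 2 * np.pi)
            width = rng.uniform(0.10, 0.2)
            amp = rng.uniform(0.02, 0.05)
            d = np.angle(np.exp(1j * (theta - c)))
            r += amp * np.exp(-0.5 * (d / width) ** 2)
    else:
        # boundary irregularity: low-order random harmonics
        for h in range(2, 7):
            amp = rng.uniform(0.0, 0.06) / np.sqrt(h)
            r *= 1.0 + amp * np.cos(h * theta + rng.uniform(0, 2 * np.pi))
        r = np.clip(r, 0.2, None)
    ang = theta + phi
    return np.column_stack([r * np.sin(ang), r * np.cos(ang)])  # (row, col) offsets


def render_organoid_image(
    organoid: SyntheticOrganoid, config: CohortConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Render one organoid as an 8-bit brightfield-like raster.

    Dark organoid blob on a light background; the outline is scaled so the
    Feret diameter of the noiseless rasterized mask matches the organoid's
    true Feret within 2 px.  Low-quality organoids receive their configured
    number of bright interior discs (cysts); high-quality organoids get
    small peripheral buds.  Returns ``(image, cyst_mask)`` and stores both
    on the organoid.  Deterministic given the organoid's render seed.
    """
    h, w = config.image_shape
    target_px = organoid.true_features["feret_um"] / config.pixel_size_um
    if target_px >= min(h, w) - 4:
        raise RenderError(
            f"{organoid.organoid_id}: Feret {target_px:.0f} px does not fit the "
            f"{h}x{w} canvas at {config.pixel_size_um} um/px"
        )
    rng = np.random.default_rng(organoid.render_seed)
    poly = _shape_polygon(rng, organoid.true_quality, organoid.true_features["aspect_ratio"])

    mask = np.zeros((h, w), dtype=bool)
    scale = target_px / max_feret_distance(poly)
    center = np.array([h / 2.0, w / 2.0])
    for _ in range(4):  # refine scale so the *rasterized* mask hits the target
        pts = poly * scale + center
        rr, cc = draw_polygon(pts[:, 0], pts[:, 1], shape=(h, w))
        mask = np.zeros((h, w), dtype=bool)
        mask[rr, cc] = True
        measured = max_feret_distance(np.column_stack(np.nonzero(mask)))
        if abs(measured - target_px) <= 1.0:
            break
        scale *= target_px / measured

    cyst_mask = _place_cysts(rng, mask, organoid.true_features["cysts_count"], config)

    img = np.full((h, w), 220.0)
    img[mask] = 90.0
    img[cyst_mask] = 185.0
    img += rng.normal(0.0, 3.0, size=img.shape)
    image = np.clip(img, 0, 255).astype(np.uint8)
    organoid.image = image
    organoid.cyst_mask = cyst_mask
    return image, cyst_mask


def _place_cysts(
    rng: np.random.Generator, mask: np.ndarray, n_cysts: int, config: CohortConfig
) -> np.ndarray:
    """Place exactly ``n_cysts`` non-overlapping bright discs inside the mask."""
    cyst_mask = np.zeros_like(mask)
    if n_cysts == 0:
        return cyst_mask
    interior = np.column_stack(np.nonzero(mask))
    h, w = mask.shape
    radius = 12
    placed = 0
    attempts = 0
    while placed < n_cysts:
        attempts += 1
        if attempts > 400:
            radius = max(3, radius - 2)  # shrink until discs fit
            attempts = 0
        r0, c0 = interior[rng.integers(len(interior))]
        rr, cc = draw_disk((r0, c0), radius + 2, shape=(h, w))
        if not mask[rr, cc].all() or cyst_mask[rr, cc].any():
            continue
        rr, cc = draw_disk((r0, c0), radius, shape=(h, w))
        cyst_mask[rr, cc] = True
        placed += 1
    return cyst_mask


# ---------------------------------------------------------------------------
# Expression and fluorescence


def make_signature(
    n_genes: int = 2000, cell_types: list[str] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Synthetic genes x cell-types signature matrix.

    Lognormal baseline expression shared across types, plus a dedicated
    block of strongly up-regulated marker genes per cell type so the
    mixture problem is well conditioned — a synthetic stand-in for a
    single-cell reference atlas signature.
    """
    cell_types = list(cell_types or CELL_TYPES)
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=3.0, sigma=1.0, size=(n_genes, len(cell_types)))
    block = n_genes // (len(cell_types) * 2)
    for j in range(len(cell_types)):
        lo = j * block
        base[lo : lo + block, j] *= 25.0
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    return pd.DataFrame(base, index=genes, columns=cell_types)


def generate_expression_mixture(
    fractions: np.ndarray,
    signature: pd.DataFrame,
    noise_cv: float,
    seed: int,
) -> np.ndarray:
    """Bulk expression vector: signature . fractions x multiplicative noise.

    The noise is i.i.d. lognormal with unit mean and coefficient of
    variation ``noise_cv``; ``noise_cv=0`` returns the exact linear mixture.
    """
    fractions = np.asarray(fractions, dtype=float)
    if (fractions < 0).any():
        raise DomainError("fractions must be non-negative")
    if len(fractions) != signature.shape[1]:
        raise DomainError("fractions length must equal the signature column count")
    clean = signature.to_numpy() @ fractions
    if noise_cv == 0:
        return clean
    sigma2 = np.log1p(noise_cv**2)
    rng = np.random.default_rng(seed)
    noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=clean.shape)
    return clean * noise


DEFAULT_CHANNEL_COUPLING = {
    # (baseline MFI, slope per unit MC fraction, noise SD)
    "CD73": (20.0, 120.0, 9.0),
    "CD105": (15.0, 110.0, 8.0),
    "MAP2": (80.0, -40.0, 12.0),
}


def generate_fluorescence_panel(
    cohort: list[SyntheticOrganoid],
    coupling: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-organoid mean fluorescence intensities for the MC-marker panel.

    MFI(channel) = baseline + slope * MC_fraction + Gaussian noise, floored
    at 0.  Positive slopes on both CD markers induce the positive
    CD73-CD105 correlation seen with genuinely coupled markers.  Also
    records a per-section Feret (a noisy half-scale view of the whole-mount
    Feret, as cryosections rarely pass through the widest plane).
    """
    coupling = coupling or DEFAULT_CHANNEL_COUPLING
    for params in coupling.values():
        if not all(np.isfinite(params)):
            raise ConfigurationError("channel coupling parameters must be finite")
    rng = np.random.default_rng(seed)
    rows = []
    for org in cohort:
        mc = float(org.true_fractions[0])
        rec = {"organoid_id": org.organoid_id, "line_id": org.line_id}
        for channel, (base, slope, noise_sd) in coupling.items():
            mfi = max(0.0, base + slope * mc + rng.normal(0.0, noise_sd))
            rec[f"mfi_{channel}"] = mfi
        rec["section_feret_um"] = org.true_features["feret_um"] * float(
            rng.uniform(0.55, 0.95)
        )
        org.fluorescence_truth = {k: v for k, v in rec.items() if k not in ("organoid_id", "line_id")}
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort IO


def write_cohort(
    cohort: list[SyntheticOrganoid],
    config: CohortConfig,
    out_dir: str | Path,
    *,
    render_images: bool = True,
    signature: pd.DataFrame | None = None,
) -> Path:
    """Write a cohort to disk: images/ (8-bit TIFF), truth.csv,
    expression.csv (genes x samples), signature.csv and cohort.cfg."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if render_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for org in cohort:
            if org.image is None:
                render_organoid_image(org, config)
            tifffile.imwrite(img_dir / f"{org.organoid_id}.tif", org.image)
    if signature is None:
        signature = make_signature(config.n_genes, seed=config.seed + 1)
    expr_seeds = np.random.SeedSequence([config.seed, 7]).spawn(len(cohort))
    expr = {
        org.organoid_id: generate_expression_mixture(
            org.true_fractions,
            signature,
            config.expression_noise_cv,
            int(expr_seeds[i].generate_state(1)[0] % (2**31)),
        )
        for i, org in enumerate(cohort)
    }
    pd.DataFrame(expr, index=signature.index).to_csv(out / "expression.csv")
    signature.to_csv(out / "signature.csv")
    cohort_truth_table(cohort).to_csv(out / "truth.csv", index=False)
    with open(out / "cohort.cfg", "w") as fh:
        for key, val in asdict(config).items():
            if isinstance(val, tuple):
                val = ",".join(str(v) for v in val)
            fh.write(f"{key} = {val}\n")
    return out


def load_config_file(path: str | Path) -> CohortConfig:
    """Read a flat key = value cohort configuration file."""
    raw: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        raw[key.strip()] = val.strip()
    if "seed" not in raw:
        raise ConfigurationError("config file must set a seed")
    kwargs: dict = {}
    defaults = CohortConfig()
    for key, val in raw.items():
        if not hasattr(defaults, key):
            raise ConfigurationError(f"unknown config key {key!r}")
        default = getattr(defaults, key)
        if isinstance(default, tuple):
            parsed = tuple(float(v) for v in val.split(","))
            if key == "image_shape":
                parsed = tuple(int(v) for v in parsed)
            kwargs[key] = parsed
        elif isinstance(default, int):
            kwargs[key] = int(val)
        elif isinstance(default, float):
            kwargs[key] = float(val)
        else:
            kwargs[key] = val
    cfg = CohortConfig(**kwargs)
    cfg.validate()
    return cfg
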