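"""Synthetic high-content screen generator.

Emulates a multi-well chemical-genetic screen: D compounds applied at a
single concentration to L isogenic cell lines in R replicates, read out as
well-level phenotypic features on a generalized-log scale. Every generator
returns its ground truth alongside the data so that downstream stages
(segmentation, feature selection, interaction scoring, profiling, synergy
scoring) can be tested for recovery of planted structure without any
external data.

The well-level data follow an additive model on the transformed scale,

    y[d, c, f] = mu[f] + alpha[d, f] + beta[c, f] + gamma[d, c, f] + eps,

where ``alpha`` is the compound effect, ``beta`` the cell-line effect and
``gamma`` a sparse chemical-genetic interaction tensor; ``eps`` is Gaussian
with a per-feature standard deviation. Spike-in control wells (vehicle, a
strong-kill reference playing taxol's role, and a pathway-inhibitor
reference) are placed on every plate.
"""
from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "ROLE_SAMPLE",
    "ROLE_VEHICLE",
    "ROLE_KILL",
    "ROLE_PATHWAY",
    "ANNOTATION_COLUMNS",
    "PHENOTYPE_PRESETS",
    "PackingError",
    "ScreenDesign",
    "GroundTruth",
    "gen_screen_design",
    "gen_ground_truth",
    "gen_class_structured_truth",
    "gen_feature_tables",
    "inject_bad_wells",
    "gen_well_images",
    "gen_combination_grid",
    "gen_compound_annotations",
    "gen_selection_tables",
    "make_feature_names",
]

# Control roles of a well. The kill reference anchors the cell-number
# normalization at 0, the vehicle (solvent) wells anchor it at 1.
ROLE_SAMPLE = "sample"
ROLE_VEHICLE = "vehicle"
ROLE_KILL = "kill_reference"
ROLE_PATHWAY = "pathway_reference"
ROLES = (ROLE_SAMPLE, ROLE_VEHICLE, ROLE_KILL, ROLE_PATHWAY)

ANNOTATION_COLUMNS = [
    "plate",
    "well",
    "compound_id",
    "conc_uM",
    "cell_line",
    "replicate",
    "role",
]

PLATE_FORMATS = {96: (8, 12), 384: (16, 24)}


class PackingError(ValueError):
    """Requested cells cannot be placed without violating the packing limit."""


# ---------------------------------------------------------------------------
# Screen design
# ---------------------------------------------------------------------------


@dataclass
class ScreenDesign:
    """Plate/well layout of a screen.

    ``wells`` holds one record per well with the columns in
    :data:`ANNOTATION_COLUMNS`. Compound wells carry a compound identifier;
    control wells carry their role name as the compound identifier.
    """

    wells: pd.DataFrame
    plate_format: int

    @property
    def compounds(self) -> list[str]:
        mask = self.wells["role"] == ROLE_SAMPLE
        return sorted(self.wells.loc[mask, "compound_id"].unique())

    @property
    def lines(self) -> list[str]:
        return sorted(self.wells["cell_line"].unique())

    @property
    def plates(self) -> list[str]:
        return sorted(self.wells["plate"].unique())

    @property
    def n_replicates(self) -> int:
        return int(self.wells["replicate"].nunique())

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("a screen design needs at least 2 replicates")
        by_plate = self.wells.groupby("plate")["role"]
        for plate, roles in by_plate:
            present = set(roles)
            if ROLE_VEHICLE not in present or ROLE_KILL not in present:
                raise ValueError(
                    f"plate {plate!r} lacks vehicle or kill-reference controls"
                )
        samples = self.wells[self.wells["role"] == ROLE_SAMPLE]
        counts = samples.groupby(["compound_id", "cell_line", "replicate"]).size()
        expected = len(self.compounds) * len(self.lines) * self.n_replicates
        if len(counts) != expected:
            raise ValueError(
                "not every (compound, cell line) pair is present in every replicate"
            )

    def to_tsv(self, path) -> None:
        self.wells.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, plate_format: int = 384) -> "ScreenDesign":
        return cls(pd.read_csv(path, sep="\t"), plate_format)


def _well_names(plate_format: int) -> list[str]:
    n_rows, n_cols = PLATE_FORMATS[plate_format]
    rows = string.ascii_uppercase[:n_rows]
    return [f"{r}{c:02d}" for r in rows for c in range(1, n_cols + 1)]


def gen_screen_design(
    n_compounds: int,
    n_lines: int,
    n_replicates: int = 2,
    plate_format: int = 384,
    concentration: float = 5.0,
    n_vehicle: int = 16,
    n_kill: int = 8,
    n_pathway: int = 4,
    seed: int = 0,
) -> ScreenDesign:
    """Lay out a screen of ``n_compounds`` x ``n_lines`` x ``n_replicates``.

    Each plate hosts one (cell line, replicate) combination and a chunk of
    compounds; vehicle, kill-reference and pathway-reference control wells
    are placed at random positions on every plate. If the compounds do not
    fit on one plate the layout extends to additional plates (never silently
    truncates). Deterministic for a fixed ``seed``.
    """
    if plate_format not in PLATE_FORMATS:
        raise ValueError(f"unsupported plate format {plate_format}; use 96 or 384")
    if n_compounds < 1 or n_lines < 1:
        raise ValueError("need at least one compound and one cell line")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    capacity = plate_format - (n_vehicle + n_kill + n_pathway)
    if capacity < 1:
        raise ValueError("control wells leave no room for compounds on a plate")

    rng = np.random.default_rng(seed)
    well_names = _well_names(plate_format)
    compounds = [f"C{i + 1:04d}" for i in range(n_compounds)]
    lines = [f"L{i + 1:02d}" for i in range(n_lines)]
    n_chunks = -(-n_compounds // capacity)  # ceil

    records = []
    for rep in range(1, n_replicates + 1):
        for line in lines:
            for chunk in range(n_chunks):
                chunk_compounds = compounds[chunk * capacity : (chunk + 1) * capacity]
                plate = f"{line}_r{rep}_p{chunk + 1:02d}"
                entries = (
                    [(c, ROLE_SAMPLE, concentration) for c in chunk_compounds]
                    + [(ROLE_VEHICLE, ROLE_VEHICLE, 0.0)] * n_vehicle
                    + [(ROLE_KILL, ROLE_KILL, concentration)] * n_kill
                    + [(ROLE_PATHWAY, ROLE_PATHWAY, concentration)] * n_pathway
                )
                positions = rng.permutation(len(well_names))[: len(entries)]
                for (cid, role, conc), pos in zip(entries, positions):
                    records.append(
                        (plate, well_names[pos], cid, conc, line, rep, role)
                    )
    wells = pd.DataFrame(records, columns=ANNOTATION_COLUMNS)
    design = ScreenDesign(wells=wells, plate_format=plate_format)
    design.validate()
    return design


# ---------------------------------------------------------------------------
# Ground truth and feature tables
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Planted effects of a synthetic screen, all on the glog scale."""

    compounds: list[str]
    lines: list[str]
    features: list[str]
    mu: np.ndarray  # (F,)
    alpha: np.ndarray  # (D, F) compound effects
    beta: np.ndarray  # (L, F) cell-line effects
    gamma: np.ndarray  # (D, L, F) sparse interaction tensor
    sigma: np.ndarray  # (F,) noise standard deviation
    kill_effect: np.ndarray  # (F,) effect of the strong-kill reference
    pathway_effect: np.ndarray  # (F,) effect of the pathway reference
    seed: int = 0

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.sigma = np.broadcast_to(
            np.asarray(self.sigma, dtype=float), self.mu.shape
        ).copy()
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")
        D, L, F = len(self.compounds), len(self.lines), len(self.features)
        if self.gamma.shape != (D, L, F):
            raise ValueError("gamma shape inconsistent with design dimensions")

    def to_json(self, path) -> None:
        payload = {
            "compounds": self.compounds,
            "lines": self.lines,
            "features": self.features,
            "mu": self.mu.tolist(),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "sigma": self.sigma.tolist(),
            "kill_effect": self.kill_effect.tolist(),
            "pathway_effect": self.pathway_effect.tolist(),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = {
            k: np.asarray(payload[k])
            for k in ("mu", "alpha", "beta", "gamma", "sigma", "kill_effect", "pathway_effect")
        }
        return cls(
            compounds=payload["compounds"],
            lines=payload["lines"],
            features=payload["features"],
            seed=payload["seed"],
            **arrays,
        )


_FEATURE_STEMS = [
    "dna_int_mean",
    "dna_haralick_contrast",
    "nuc_area",
    "nuc_eccentricity",
    "cell_area",
    "cell_eccentricity",
    "actin_int_mean",
    "actin_haralick_contrast",
]


def make_feature_names(n_features: int) -> list[str]:
    """Feature names whose prefixes map onto the five phenoprint categories.

    Feature 1 is always ``cell_number``.
    """
    if n_features < 1:
        raise ValueError("need at least one feature")
    names = ["cell_number"]
    i = 0
    while len(names) < n_features:
        stem = _FEATURE_STEMS[i % len(_FEATURE_STEMS)]
        suffix = i // len(_FEATURE_STEMS)
        names.append(stem if suffix == 0 else f"{stem}_{suffix + 1}")
        i += 1
    return names


def gen_ground_truth(
    n_compounds: int,
    n_lines: int,
    n_features: int,
    alpha_sd: float = 0.5,
    beta_sd: float = 0.5,
    gamma_density: float = 0.02,
    gamma_range: tuple[float, float] = (0.5, 2.0),
    sigma: float | Sequence[float] = 0.2,
    kill_effect: float = -4.0,
    pathway_effect: float = -1.0,
    seed: int = 0,
) -> GroundTruth:
    """Draw a random ground truth for :func:`gen_feature_tables`.

    Interactions are planted on a ``gamma_density`` fraction of the
    (compound, line, feature) cells with magnitudes uniform in
    ``gamma_range`` and random sign. Defaults (effect sds 0.5, |gamma| in
    [0.5, 2] on a few percent of cells, sigma 0.2) are sized so planted
    interactions are recoverable with two replicates.
    """
    if not 0.0 <= gamma_density <= 1.0:
        raise ValueError("gamma_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    features = make_feature_names(n_features)
    compounds = [f"C{i + 1:04d}" for i in range(n_compounds)]
    lines = [f"L{i + 1:02d}" for i in range(n_lines)]

    mu = rng.normal(5.0, 1.0, size=n_features)
    mu[0] = 10.0  # glog cell count baseline, ~1000 cells
    alpha = rng.normal(0.0, alpha_sd, size=(n_compounds, n_features))
    beta = rng.normal(0.0, beta_sd, size=(n_lines, n_features))
    mask = rng.random((n_compounds, n_lines, n_features)) < gamma_density
    mag = rng.uniform(*gamma_range, size=mask.shape)
    sign = rng.choice([-1.0, 1.0], size=mask.shape)
    gamma = np.where(mask, mag * sign, 0.0)

    kill = rng.normal(0.0, 0.3, size=n_features)
    kill[0] = kill_effect
    pathway = rng.normal(0.0, 0.2, size=n_features)
    pathway[0] = pathway_effect
    return GroundTruth(
        compounds=compounds,
        lines=lines,
        features=features,
        mu=mu,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        sigma=np.broadcast_to(np.asarray(sigma, float), (n_features,)),
        kill_effect=kill,
        pathway_effect=pathway,
        seed=seed,
    )


def gen_class_structured_truth(
    n_lines: int,
    n_features: int,
    n_classes: int = 8,
    class_size: int = 5,
    n_inert: int = 30,
    growth_fraction: float = 0.5,
    growth_scale: float = 1.5,
    morph_scale: float = 1.2,
    member_jitter: float = 0.15,
    sigma: float = 0.2,
    seed: int = 0,
) -> tuple[GroundTruth, pd.DataFrame]:
    """Ground truth whose interactions carry target-class structure.

    The screen holds ``n_classes * class_size`` active compounds grouped
    into target classes plus ``n_inert`` inert compounds (no interaction
    signal), mirroring the sparse-active composition of real bioactive
    libraries. Members of a class share a rank-one interaction signature
    gamma = psi (over lines) x phi (over features), plus small
    member-specific jitter. Roughly ``growth_fraction`` of the classes act
    through cell number across genotypes (pharmacogenetic signal) and the
    rest through morphology features (phenotypic signal). Returns the
    truth plus a target annotation table (``compound_id``, ``target``)
    covering the active compounds only.
    """
    rng = np.random.default_rng(seed)
    n_active = n_classes * class_size
    n_compounds = n_active + n_inert
    truth = gen_ground_truth(
        n_compounds,
        n_lines,
        n_features,
        gamma_density=0.0,
        sigma=sigma,
        seed=seed + 1,
    )
    n_growth = int(round(n_classes * growth_fraction))
    gamma = np.zeros_like(truth.gamma)
    classes = [f"T{k + 1:02d}" for k in range(n_classes)]
    assignment = [classes[i // class_size] for i in range(n_active)]

    signatures = {}
    for k, cls in enumerate(classes):
        psi = rng.normal(0.0, 1.0, size=n_lines)
        phi = np.zeros(n_features)
        if k < n_growth:  # genotype-driven class: signal on cell number
            phi[0] = growth_scale
            phi[1:] = rng.normal(0.0, 0.05, size=n_features - 1)
        else:  # morphology-driven class: no cell-number signal
            phi[1:] = rng.normal(0.0, 1.0, size=n_features - 1)
            phi[1:] *= morph_scale / max(np.linalg.norm(phi[1:]) / np.sqrt(n_features - 1), 1e-9)
        signatures[cls] = np.outer(psi, phi)
    for i, cls in enumerate(assignment):
        gamma[i] = signatures[cls] + rng.normal(0.0, member_jitter, size=(n_lines, n_features))
    truth.gamma = gamma
    targets = pd.DataFrame(
        {"compound_id": truth.compounds[:n_active], "target": assignment}
    )
    return truth, targets


def gen_feature_tables(
    design: ScreenDesign,
    truth: GroundTruth,
) -> tuple[list[pd.DataFrame], GroundTruth]:
    """Simulate well-level feature tables, one table per replicate.

    Each table has the annotation columns of the design followed by one
    column per feature; values follow the additive glog-scale model with
    i.i.d. Gaussian noise of sd ``truth.sigma``. Control wells receive the
    control effects from the truth (vehicle: none; kill reference: strong
    cell-number loss). Deterministic for a fixed truth seed.
    """
    if design.compounds != truth.compounds:
        raise ValueError("design and truth disagree on compounds")
    if design.lines != truth.lines:
        raise ValueError("design and truth disagree on cell lines")
    d_index = {c: i for i, c in enumerate(truth.compounds)}
    l_index = {l: i for i, l in enumerate(truth.lines)}
    F = len(truth.features)

    tables = []
    for rep in sorted(design.wells["replicate"].unique()):
        sub = (
            design.wells[design.wells["replicate"] == rep]
            .sort_values(["plate", "well"])
            .reset_index(drop=True)
        )
        rng = np.random.default_rng([truth.seed % (2**31), int(rep)])
        n = len(sub)
        values = np.tile(truth.mu, (n, 1))
        line_idx = sub["cell_line"].map(l_index).to_numpy()
        values += truth.beta[line_idx]
        roles = sub["role"].to_numpy()
        is_sample = roles == ROLE_SAMPLE
        comp_idx = np.array(
            [d_index[c] if s else 0 for c, s in zip(sub["compound_id"], is_sample)]
        )
        values[is_sample] += truth.alpha[comp_idx[is_sample]]
        values[is_sample] += truth.gamma[comp_idx[is_sample], line_idx[is_sample]]
        values[roles == ROLE_KILL] += truth.kill_effect
        values[roles == ROLE_PATHWAY] += truth.pathway_effect
        values += rng.normal(0.0, 1.0, size=(n, F)) * truth.sigma
        table = pd.concat(
            [sub, pd.DataFrame(values, columns=truth.features)], axis=1
        )
        tables.append(table)
    return tables, truth


def inject_bad_wells(
    table: pd.DataFrame,
    n_blank: int = 0,
    n_saturated: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Corrupt sample wells to emulate failed acquisitions for QC testing.

    Blank wells get zeroed features (no cells, no signal); saturated wells
    get a ``saturated_frac`` above the QC threshold. A ``saturated_frac``
    column is added (0 elsewhere) if absent. Returns the corrupted copy and
    the affected row indices. The injected failure modes are generic, not a
    reconstruction of any particular screen's QC criteria.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    if "saturated_frac" not in out.columns:
        out["saturated_frac"] = 0.0
    feature_cols = [
        c for c in out.columns if c not in ANNOTATION_COLUMNS + ["saturated_frac", "qc_flag"]
    ]
    candidates = np.flatnonzero((out["role"] == ROLE_SAMPLE).to_numpy())
    picks = rng.choice(candidates, size=n_blank + n_saturated, replace=False)
    blank = picks[:n_blank]
    saturated = picks[n_blank:]
    out.loc[out.index[blank], feature_cols] = 0.0
    out.loc[out.index[saturated], "saturated_frac"] = 0.5
    return out, {"blank": out.index[blank].tolist(), "saturated": out.index[saturated].tolist()}


# ---------------------------------------------------------------------------
# Synthetic well images
# ---------------------------------------------------------------------------

#: Parameter presets for qualitative phenotypes. ``apoptotic`` renders
#: small bright nuclei, ``enlarged`` big nuclei/cells, ``elongated``
#: stretched cell bodies.
PHENOTYPE_PRESETS: dict[str, dict] = {
    "normal": {},
    "apoptotic": {"nuclear_radius": 3.5, "dna_level": 45000, "cell_scale": 1.6},
    "enlarged": {"nuclear_radius": 9.0, "cell_scale": 2.5},
    "elongated": {"elongation": 2.5},
}


def gen_well_images(
    n_cells: int,
    image_size: int = 256,
    nuclear_radius: float = 6.0,
    nuclear_eccentricity: float = 0.3,
    cell_scale: float = 2.2,
    elongation: float = 1.0,
    dna_level: float = 30000.0,
    actin_level: float = 18000.0,
    background: float = 2000.0,
    texture_scale: float = 0.15,
    noise_sd: float = 200.0,
    border: int = 0,
    packing_limit: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Render a two-channel (DNA, actin) 16-bit well image.

    One bright elliptical nucleus per cell in the DNA channel, a larger
    actin body enclosing each nucleus in the actin channel. Cells are placed
    on a jittered grid so they never overlap; ``border`` > 0 adds a dark
    frame emulating reduced illumination at the image edge. Returns the
    image stack of shape (2, H, W) and a ground-truth dict with the planted
    centers and geometry.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")
    rng = np.random.default_rng(seed)
    cell_radius = nuclear_radius * cell_scale * max(elongation, 1.0)
    sep = 2.0 * cell_radius + 4.0
    inner = image_size - 2 * border
    if n_cells > 0:
        if n_cells * np.pi * cell_radius**2 > packing_limit * inner**2:
            raise PackingError(
                f"{n_cells} cells of radius {cell_radius:.1f} exceed the packing "
                f"limit {packing_limit} of a {inner}x{inner} field"
            )
        n_grid = int(inner // sep)
        if n_grid**2 < n_cells:
            raise PackingError(
                f"cannot place {n_cells} non-overlapping cells with separation "
                f"{sep:.1f} in a {inner}x{inner} field (capacity {n_grid ** 2})"
            )

    dna = np.full((image_size, image_size), background, dtype=float)
    actin = np.full((image_size, image_size), background, dtype=float)
    centers, radii, angles = [], [], []
    if n_cells > 0:
        from skimage.draw import ellipse as draw_ellipse

        slots = rng.choice(n_grid**2, size=n_cells, replace=False)
        jitter_amp = max((sep - 2.0 * cell_radius) / 2.0 - 1.0, 0.0)
        ecc = float(np.clip(nuclear_eccentricity, 0.0, 0.95))
        stretch = (1.0 - ecc**2) ** 0.25
        for slot in slots:
            gy, gx = divmod(int(slot), n_grid)
            cy = border + (gy + 0.5) * sep + rng.uniform(-jitter_amp, jitter_amp)
            cx = border + (gx + 0.5) * sep + rng.uniform(-jitter_amp, jitter_amp)
            theta = rng.uniform(0.0, np.pi)
            a_n = nuclear_radius / stretch
            b_n = nuclear_radius * stretch
            rr, cc = draw_ellipse(cy, cx, a_n, b_n, shape=dna.shape, rotation=theta)
            dna[rr, cc] = dna_level
            a_c = a_n * cell_scale * elongation
            b_c = b_n * cell_scale
            rr, cc = draw_ellipse(cy, cx, a_c, b_c, shape=actin.shape, rotation=theta)
            actin[rr, cc] = actin_level
            centers.append((cy, cx))
            radii.append(nuclear_radius)
            angles.append(theta)
        # stain the cytoplasm over the nucleus too, but dimmer
        actin[dna > background] = np.maximum(actin[dna > background], actin_level * 0.6)

    if texture_scale > 0:
        for img, level in ((dna, dna_level), (actin, actin_level)):
            tex = ndi.gaussian_filter(rng.normal(0.0, 1.0, img.shape), 2.0)
            tex /= max(np.abs(tex).max(), 1e-9)
            fg = img > background
            img[fg] *= 1.0 + texture_scale * tex[fg]
    if noise_sd > 0:
        dna += rng.normal(0.0, noise_sd, dna.shape)
        actin += rng.normal(0.0, noise_sd, actin.shape)
    if border > 0:
        frame = np.zeros((image_size, image_size), dtype=bool)
        frame[:border, :] = frame[-border:, :] = True
        frame[:, :border] = frame[:, -border:] = True
        dna[frame] *= 0.25
        actin[frame] *= 0.25

    stack = np.stack(
        [np.clip(dna, 0, 65535).astype(np.uint16), np.clip(actin, 0, 65535).astype(np.uint16)]
    )
    truth = {
        "centers": np.array(centers).reshape(-1, 2),
        "nuclear_radius": np.array(radii),
        "orientation": np.array(angles),
        "n_cells": n_cells,
        "border": border,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# Drug-combination grids
# ---------------------------------------------------------------------------


def gen_combination_grid(
    effect_a: Callable[[np.ndarray], np.ndarray] | Sequence[float],
    effect_b: Callable[[np.ndarray], np.ndarray] | Sequence[float],
    interaction: float | Sequence[float] = 0.0,
    n_doses: int = 10,
    top_dose: float = 10.0,
    dilution_factor: float = 2.0,
    n_rep_single: int = 20,
    n_rep_combo: int = 10,
    n_rep_control: int = 16,
    noise_sd: float = 0.05,
    log_neg: float = np.log(1e6),
    log_pos: float = np.log(1e4),
    seed: int = 0,
):
    """Simulate a fixed-ratio dilution series for a compound pair.

    Single-agent effects E_A, E_B (on the normalized 0..1 effect scale,
    1 = full kill) are given per dose; the combination is generated under
    the Bliss model E_AB = E_A + E_B - E_A:B with the planted
    ``interaction`` term (0 = independence; negative = synergy). Raw
    plate-reader intensities are produced on the log scale anchored at the
    negative (untreated, high signal) and positive (full-kill, low signal)
    control levels, with log-normal measurement noise. Returns a
    :class:`phenoscreen.combinations.CombinationGrid` whose truth records
    the planted per-dose effects.
    """
    from .combinations import CombinationGrid

    if n_doses < 1:
        raise ValueError("n_doses must be >= 1")
    if dilution_factor <= 1:
        raise ValueError("dilution_factor must exceed 1")
    rng = np.random.default_rng(seed)
    doses = top_dose / dilution_factor ** np.arange(n_doses)

    def _eval(eff, doses):
        if callable(eff):
            return np.asarray(eff(doses), dtype=float)
        arr = np.asarray(eff, dtype=float)
        if arr.shape != doses.shape:
            raise ValueError("per-dose effect vector length must match n_doses")
        return arr

    e_a = _eval(effect_a, doses)
    e_b = _eval(effect_b, doses)
    e_ab_int = np.broadcast_to(np.asarray(interaction, dtype=float), doses.shape)
    e_ab = e_a + e_b - e_ab_int

    span = log_pos - log_neg  # negative for a kill readout
    rows = []
    for i, dose in enumerate(doses):
        for arm, eff, nrep in (
            ("A", e_a[i], n_rep_single),
            ("B", e_b[i], n_rep_single),
            ("AB", e_ab[i], n_rep_combo),
        ):
            log_raw = log_neg + eff * span + rng.normal(0.0, noise_sd, nrep)
            for r, v in enumerate(log_raw, start=1):
                rows.append((dose, arm, r, float(np.exp(v))))
    for arm, level in (("pos", log_pos), ("neg", log_neg)):
        log_raw = level + rng.normal(0.0, noise_sd, n_rep_control)
        for r, v in enumerate(log_raw, start=1):
            rows.append((np.nan, arm, r, float(np.exp(v))))
    data = pd.DataFrame(rows, columns=["dose_uM", "arm", "replicate", "raw_value"])
    truth = pd.DataFrame(
        {"dose_uM": doses, "E_A": e_a, "E_B": e_b, "E_AB": e_ab, "interaction": e_ab_int}
    )
    return CombinationGrid(data=data, truth=truth)


# ---------------------------------------------------------------------------
# Compound annotations and structural distances
# ---------------------------------------------------------------------------


def gen_compound_annotations(
    n_compounds: int,
    n_target_classes: int = 4,
    structure_noise: float = 0.1,
    within_distance: float = 0.3,
    between_distance: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Target-class annotations plus a matching pairwise distance matrix.

    Compounds are assigned to target classes round-robin; the synthetic
    structural distance places same-class pairs around ``within_distance``
    and cross-class pairs around ``between_distance`` (fingerprint-distance
    convention: symmetric, zero diagonal, values in [0, 1]), with uniform
    perturbations scaled by ``structure_noise``.
    """
    if n_target_classes < 1:
        raise ValueError("need at least one target class")
    rng = np.random.default_rng(seed)
    compounds = [f"C{i + 1:04d}" for i in range(n_compounds)]
    classes = [f"T{(i % n_target_classes) + 1:02d}" for i in range(n_compounds)]
    targets = pd.DataFrame({"compound_id": compounds, "target": classes})

    dist = np.zeros((n_compounds, n_compounds))
    for i in range(n_compounds):
        for j in range(i + 1, n_compounds):
            base = within_distance if classes[i] == classes[j] else between_distance
            d = base + structure_noise * rng.uniform(-1.0, 1.0)
            dist[i, j] = dist[j, i] = float(np.clip(d, 0.0, 1.0))
    distances = pd.DataFrame(dist, index=compounds, columns=compounds)
    return targets, distances


# ---------------------------------------------------------------------------
# Replicate tables for the feature-selection benchmark
# ---------------------------------------------------------------------------


def gen_selection_tables(
    n_wells: int = 500,
    n_signals: int = 20,
    n_combos: int = 40,
    n_noise: int = 40,
    signal_sd: float = 1.0,
    replicate_noise_sd: float = 1.0 / 3.0,
    combo_weight_sd: float = 0.3,
    combo_noise_sd: float = 0.4,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two replicate tables with a known informative-feature dimension.

    ``n_signals`` features are independent latent signals observed in both
    replicates with independent measurement noise (replicate correlation
    s^2/(s^2+n^2), ~0.9 at the defaults); ``n_combos`` features are exact
    linear combinations of the *observed* signal features plus small
    feature-specific noise, so they carry no information beyond the signals;
    ``n_noise`` features are pure replicate-independent noise. The first
    signal is named ``cell_number`` to serve as the selection start. Returns
    (rep1, rep2, truth-dict).
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, signal_sd, size=(n_wells, n_signals))
    x1 = z + rng.normal(0.0, replicate_noise_sd, z.shape)
    x2 = z + rng.normal(0.0, replicate_noise_sd, z.shape)
    w = rng.normal(0.0, combo_weight_sd, size=(n_signals, n_combos))
    c1 = x1 @ w + rng.normal(0.0, combo_noise_sd, size=(n_wells, n_combos))
    c2 = x2 @ w + rng.normal(0.0, combo_noise_sd, size=(n_wells, n_combos))
    u1 = rng.normal(0.0, noise_sd, size=(n_wells, n_noise))
    u2 = rng.normal(0.0, noise_sd, size=(n_wells, n_noise))

    signal_names = ["cell_number"] + [f"sig_{i:02d}" for i in range(1, n_signals)]
    combo_names = [f"combo_{i:02d}" for i in range(n_combos)]
    noise_names = [f"noise_{i:02d}" for i in range(n_noise)]
    columns = signal_names + combo_names + noise_names
    rep1 = pd.DataFrame(np.hstack([x1, c1, u1]), columns=columns)
    rep2 = pd.DataFrame(np.hstack([x2, c2, u2]), columns=columns)
    truth = {
        "signal_features": signal_names,
        "combo_features": combo_names,
        "noise_features": noise_names,
        "weights": w,
    }
    return rep1, rep2, truth
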