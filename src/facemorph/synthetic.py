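"""Synthetic facial landmark datasets with planted ground truth.

The generator emulates the structure the downstream analysis assumes: a
bilaterally symmetric 97-point facial template partitioned into brow, eye,
pupil, nose, mouth, and chin groups (76 outline points carry slider
definitions); per-species mean-shape offsets; named age-class effect axes
(eye enlargement + lowering, vertical compression, top-heaviness) applied to
infants; isotropic Gaussian digitization noise; and nuisance similarity
transforms (rotation, scale, translation) removed later by Procrustes
superimposition.

Everything is expressed in unit-centroid-size shape units: the template is
centered and scaled to centroid size 1, effect axes are unit vectors
orthogonal to the similarity-transform subspace, and ``noise_sigma`` is the
per-coordinate landmark noise on that scale.

Template group layout (a documented constant of the module)::

    brow 17 | left_eye 10 | right_eye 10 | left_pupil 1 | right_pupil 1
    left_nose_edge 8 | right_nose_edge 8 | nasion 1 | nose_tip 1
    left_nostril 1 | right_nostril 1 | philtrum 1 | mouth 22 | chin 15

Semilandmarks (76): open arcs slide their interior points; the closed eye
and mouth outlines slide every point except their two fixed corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from facemorph.tps_io import (
    AGE_CLASSES,
    SPECIES,
    LandmarkConfiguration,
    LandmarkDataset,
    SliderTable,
    SpecimenMetadata,
    validate_dataset,
)

K = 97
N_SLIDERS = 76

# ---------------------------------------------------------------- template

_GROUP_SIZES = {
    "brow": 17,
    "left_eye": 10,
    "right_eye": 10,
    "left_pupil": 1,
    "right_pupil": 1,
    "left_nose_edge": 8,
    "right_nose_edge": 8,
    "nasion": 1,
    "nose_tip": 1,
    "left_nostril": 1,
    "right_nostril": 1,
    "philtrum": 1,
    "mouth": 22,
    "chin": 15,
}


def template_groups() -> dict[str, np.ndarray]:
    """Landmark index ranges per named facial group."""
    groups = {}
    start = 0
    for name, size in _GROUP_SIZES.items():
        groups[name] = np.arange(start, start + size)
        start += size
    assert start == K
    return groups


def _arc(x0: float, x1: float, y_base: float, bulge: float, n: int) -> np.ndarray:
    """Symmetric parabolic arc sampled at n equally spaced x positions."""
    x = np.linspace(x0, x1, n)
    half = (x1 - x0) / 2.0
    mid = (x0 + x1) / 2.0
    y = y_base + bulge * (1.0 - ((x - mid) / half) ** 2)
    return np.column_stack([x, y])


def _ellipse(cx: float, cy: float, a: float, b: float, n: int) -> np.ndarray:
    """Closed ellipse outline; point 0 at angle 0, counter-clockwise."""
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([cx + a * np.cos(theta), cy + b * np.sin(theta)])


def template_face() -> LandmarkConfiguration:
    """The schematic 97-landmark face, centered, unit centroid size.

    Bilaterally symmetric about the vertical midline: reflecting x -> -x
    permutes left/right groups onto each other.
    """
    parts = {
        "brow": _arc(-0.45, 0.45, 0.35, 0.13, 17),
        "left_eye": None,
        "right_eye": _ellipse(0.22, 0.18, 0.11, 0.055, 10),
        "left_pupil": np.array([[-0.22, 0.18]]),
        "right_pupil": np.array([[0.22, 0.18]]),
        "left_nose_edge": None,
        "right_nose_edge": None,
        "nasion": np.array([[0.0, 0.30]]),
        "nose_tip": np.array([[0.0, 0.0]]),
        "left_nostril": np.array([[-0.13, -0.04]]),
        "right_nostril": np.array([[0.13, -0.04]]),
        "philtrum": np.array([[0.0, -0.10]]),
        "mouth": _ellipse(0.0, -0.16, 0.17, 0.06, 22),
        "chin": _arc(-0.28, 0.28, -0.26, -0.16, 15),
    }
    # left eye is the mirror of the right eye (exact point-set symmetry)
    parts["left_eye"] = parts["right_eye"] * np.array([-1.0, 1.0])
    # nose edges: gentle outward-curving verticals from bridge to nostril level
    t = np.linspace(0.0, 1.0, 8)
    xr = 0.06 + 0.04 * t + 0.02 * np.sin(np.pi * t)
    yr = 0.22 - 0.24 * t
    parts["right_nose_edge"] = np.column_stack([xr, yr])
    parts["left_nose_edge"] = parts["right_nose_edge"] * np.array([-1.0, 1.0])

    pts = np.vstack([parts[name] for name in _GROUP_SIZES])
    pts = pts - pts.mean(axis=0)
    pts = pts / np.sqrt(np.sum(pts**2))
    return LandmarkConfiguration(specimen_id="template", points=pts)


def template_sliders() -> SliderTable:
    """Slider triplets for the template's 76 outline semilandmarks.

    Open arcs (brow, nose edges, chin): interior points slide between their
    neighbours.  Closed outlines (eyes, mouth): the two corner points at
    parameter angles 0 and pi are fixed; all others slide between their
    cyclic neighbours.
    """
    groups = template_groups()
    triplets: list[tuple[int, int, int]] = []

    def open_arc(idx: np.ndarray) -> None:
        for j in range(1, len(idx) - 1):
            triplets.append((idx[j - 1], idx[j], idx[j + 1]))

    def closed(idx: np.ndarray, fixed_local: tuple[int, int]) -> None:
        m = len(idx)
        for j in range(m):
            if j in fixed_local:
                continue
            triplets.append((idx[(j - 1) % m], idx[j], idx[(j + 1) % m]))

    open_arc(groups["brow"])
    closed(groups["left_eye"], (0, 5))   # outer/inner eye corners
    closed(groups["right_eye"], (0, 5))
    open_arc(groups["left_nose_edge"])
    open_arc(groups["right_nose_edge"])
    closed(groups["mouth"], (0, 11))     # mouth corners
    open_arc(groups["chin"])
    table = SliderTable(np.asarray(triplets, int))
    assert len(table) == N_SLIDERS
    return table


# ---------------------------------------------------------- effect axes

def similarity_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis (4, 2k) of the similarity-transform subspace at a
    centered template: x/y translation, scaling, and infinitesimal rotation."""
    pts = np.asarray(template, float)
    k = pts.shape[0]
    tx = np.zeros(2 * k)
    tx[0::2] = 1.0
    ty = np.zeros(2 * k)
    ty[1::2] = 1.0
    centered = pts - pts.mean(axis=0)
    scale = centered.reshape(-1)
    rot = np.column_stack([-centered[:, 1], centered[:, 0]]).reshape(-1)
    basis = np.stack([tx, ty, scale, rot])
    return basis / np.sqrt(np.sum(basis**2, axis=1))[:, None]


def remove_similarity(vec: np.ndarray, basis: np.ndarray) -> np.ndarray:
    return vec - basis.T @ (basis @ vec)


def make_age_axes(template: LandmarkConfiguration | np.ndarray) -> dict[str, np.ndarray]:
    """Named unit effect axes mimicking infantile facial shape change.

    - ``eye_enlarge_lower``: scale the eye outlines and pupils up about their
      own centroids and translate them down the face.
    - ``vertical_compress``: shrink y about the face centroid while widening
      x just enough to preserve centroid size to first order.
    - ``top_heavy``: widen the upper face and narrow the lower face (an
      inverted-triangle effect).

    Each axis is projected orthogonal to the similarity subspace and
    normalized to unit length in the flattened (x1, y1, ...) coordinates.
    """
    pts = template.points if isinstance(template, LandmarkConfiguration) else np.asarray(template, float)
    pts = pts - pts.mean(axis=0)
    groups = template_groups()
    basis = similarity_basis(pts)
    k = pts.shape[0]

    # eye enlargement + lowering
    d1 = np.zeros((k, 2))
    for side in ("left", "right"):
        idx = np.concatenate([groups[f"{side}_eye"], groups[f"{side}_pupil"]])
        center = pts[groups[f"{side}_eye"]].mean(axis=0)
        d1[idx] += pts[idx] - center          # enlarge about eye centroid
        d1[idx, 1] -= 0.08                     # lower in the face
    # vertical compression with size-preserving widening
    widen = np.sum(pts[:, 1] ** 2) / np.sum(pts[:, 0] ** 2)
    d2 = np.column_stack([widen * pts[:, 0], -pts[:, 1]])
    # top-heavy: x displacement proportional to x * y
    d3 = np.column_stack([pts[:, 0] * pts[:, 1], np.zeros(k)])

    axes = {}
    for name, d in (
        ("eye_enlarge_lower", d1),
        ("vertical_compress", d2),
        ("top_heavy", d3),
    ):
        v = remove_similarity(d.reshape(-1), basis)
        axes[name] = v / np.sqrt(np.sum(v**2))
    return axes


# ---------------------------------------------------------- simulation

#: default per-axis infant effect magnitudes, in unit-centroid-size shape units
DEFAULT_EFFECT_MAGNITUDES = {
    "eye_enlarge_lower": 0.12,
    "vertical_compress": 0.04,
    "top_heavy": 0.02,
}
DEFAULT_NOISE_SIGMA = 0.01
DEFAULT_SPECIES_OFFSET_NORM = 0.03
DEFAULT_NUISANCE = (15.0, (0.8, 1.2), 0.1)  # max rotation deg, scale range, translation


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset.

    ``age_effect_axes`` maps axis name to (unit vector, magnitude); infants
    get ``sum(magnitude * axis)`` added to their shape.  All vectors are
    orthogonal to the similarity subspace at the template.
    """

    template: np.ndarray
    species_offsets: dict[str, np.ndarray]
    age_effect_axes: dict[str, tuple[np.ndarray, float]]
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    nuisance: tuple[float, tuple[float, float], float] = DEFAULT_NUISANCE
    seed: int = 0
    sliders: SliderTable = field(default_factory=template_sliders)

    def dominant_axis(self) -> np.ndarray:
        name = max(self.age_effect_axes, key=lambda n: self.age_effect_axes[n][1])
        return self.age_effect_axes[name][0]

    def total_effect(self) -> np.ndarray:
        return sum(m * v for v, m in self.age_effect_axes.values())


def default_truth(
    seed: int = 0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    species_offset_norm: float = DEFAULT_SPECIES_OFFSET_NORM,
    effect_magnitudes: dict[str, float] | None = None,
    nuisance: tuple[float, tuple[float, float], float] = DEFAULT_NUISANCE,
) -> SyntheticTruth:
    """Study-condition truth: 5 species, 3 planted infant axes, default noise.

    Species offsets are drawn once from a seeded isotropic Gaussian in shape
    space (projected off the similarity subspace, scaled to
    ``species_offset_norm``) rather than hand-crafted: species realism is not
    needed to test the inference machinery.
    """
    template = template_face().points
    basis = similarity_basis(template)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    offsets = {}
    for sp in SPECIES:
        v = remove_similarity(rng.normal(size=2 * K), basis)
        offsets[sp] = v / np.sqrt(np.sum(v**2)) * species_offset_norm
    mags = dict(DEFAULT_EFFECT_MAGNITUDES if effect_magnitudes is None else effect_magnitudes)
    axes = make_age_axes(template)
    return SyntheticTruth(
        template=template,
        species_offsets=offsets,
        age_effect_axes={n: (axes[n], mags.get(n, 0.0)) for n in axes},
        noise_sigma=noise_sigma,
        nuisance=nuisance,
        seed=seed,
    )


def axis_in_fit_frame(axis: np.ndarray, template: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Rotate a planted shape-space axis into a Procrustes fit's frame.

    GPA output lives in a canonical orientation that generally differs from
    the template's by a rotation; recovery of a planted axis must be measured
    after applying that rotation to the axis.  Returns the rotated flattened
    axis (unit norm preserved).
    """
    from facemorph.procrustes import _center_and_scale, optimal_rotation

    (tc, cc), _ = _center_and_scale(
        np.stack([np.asarray(template, float), np.asarray(consensus, float)]), ["t", "c"]
    )
    rot = optimal_rotation(tc, cc)
    return (axis.reshape(-1, 2) @ rot).reshape(-1)


def _similarity_transform(pts: np.ndarray, rng: np.random.Generator,
                          nuisance: tuple[float, tuple[float, float], float]) -> np.ndarray:
    max_rot, scale_range, max_trans = nuisance
    angle = np.deg2rad(rng.uniform(-max_rot, max_rot))
    scale = rng.uniform(*scale_range)
    trans = rng.uniform(-max_trans, max_trans, size=2)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, s], [-s, c]])
    return scale * (pts @ rot) + trans


def simulate_dataset(
    truth: SyntheticTruth,
    n_per_cell: int = 8,
) -> tuple[LandmarkDataset, SyntheticTruth]:
    """Simulate ``n_per_cell`` specimens per species x age cell.

    Each specimen is template + species offset + (infants only) the summed
    age effects + isotropic Gaussian landmark noise, pushed through a random
    similarity transform.  Bit-reproducible under ``truth.seed``.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=truth.seed, spawn_key=(1,)))
    effect = truth.total_effect()
    configs, meta = [], []
    for sp in truth.species_offsets:
        for age in AGE_CLASSES:
            for i in range(n_per_cell):
                flat = truth.template.reshape(-1) + truth.species_offsets[sp]
                if age == "infant":
                    flat = flat + effect
                flat = flat + rng.normal(0.0, truth.noise_sigma, size=flat.size)
                pts = _similarity_transform(flat.reshape(-1, 2), rng, truth.nuisance)
                sid = f"{sp}_{age}_{i + 1}"
                configs.append(LandmarkConfiguration(specimen_id=sid, points=pts))
                meta.append(SpecimenMetadata(specimen_id=sid, species=sp, age_class=age))
    dataset = validate_dataset(LandmarkDataset(configs, meta, truth.sliders))
    return dataset, truth
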