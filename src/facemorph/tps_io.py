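"""Reading and writing TPS landmark files, slider tables, and specimen metadata.

The TPS dialect handled here is the plain 2-D landmark record format produced
by the tpsDig family of digitizing tools::

    LM=97
    123.0 456.0
    ...
    IMAGE=face_001.jpg
    ID=bonobo_infant_3
    SCALE=0.01

Records with ``CURVES=``/``POINTS=`` blocks (outline dialect) are rejected
rather than silently skipped.  SCALE lines are stored as provenance but never
applied: size is removed downstream by Procrustes superimposition, so scaling
the raw coordinates would be a no-op for shape.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("human", "chimpanzee", "bonobo", "gorilla", "orangutan")
AGE_CLASSES = ("adult", "infant")
SEXES = ("male", "female", "unknown")


class TPSParseError(ValueError):
    """Malformed TPS or slider file."""


class DatasetValidationError(ValueError):
    """A dataset-level invariant is violated; ``errors`` lists all breaches."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("dataset validation failed:\n  - " + "\n  - ".join(self.errors))


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmark configuration.

    Point order is the homology order and is never permuted by any operation
    in the package.  Coordinates follow the tpsDig convention (y increases
    upward); use ``flip_y=True`` at read time for screen-convention data.
    """

    specimen_id: str
    points: np.ndarray  # (k, 2) float
    image_name: str | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError(
                f"specimen {self.specimen_id!r}: points must be (k, 2), "
                f"got {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"specimen {self.specimen_id!r}: non-finite coordinate")
        if self.scale is not None and self.scale <= 0:
            raise ValueError(f"specimen {self.specimen_id!r}: SCALE must be positive")

    @property
    def k(self) -> int:
        return self.points.shape[0]


@dataclass
class SliderTable:
    """Semilandmark slider definitions as (before, slider, after) index triplets.

    Indices are 0-based into the landmark order.  The slider point is allowed
    to move along the chord from its *before* to its *after* neighbour during
    semilandmark sliding.
    """

    triplets: np.ndarray  # (s, 3) int

    def __post_init__(self) -> None:
        self.triplets = np.asarray(self.triplets, dtype=int)
        if self.triplets.size == 0:
            self.triplets = self.triplets.reshape(0, 3)
        if self.triplets.ndim != 2 or self.triplets.shape[1] != 3:
            raise ValueError(f"triplets must be (s, 3), got {self.triplets.shape}")
        before, slider, after = self.triplets.T
        if np.any(before == slider) or np.any(after == slider):
            bad = self.triplets[(before == slider) | (after == slider)]
            raise ValueError(f"slider index equals its neighbour in triplet(s) {bad.tolist()}")
        uniq, counts = np.unique(slider, return_counts=True)
        if np.any(counts > 1):
            raise ValueError(f"duplicate slider indices: {uniq[counts > 1].tolist()}")
        if self.triplets.size and self.triplets.min() < 0:
            raise ValueError("negative slider index")

    def __len__(self) -> int:
        return self.triplets.shape[0]

    @property
    def slider_indices(self) -> np.ndarray:
        return self.triplets[:, 1]

    def validate_for_k(self, k: int) -> None:
        if self.triplets.size and self.triplets.max() >= k:
            raise ValueError(
                f"slider index {int(self.triplets.max())} out of range for k={k}"
            )


@dataclass
class SpecimenMetadata:
    specimen_id: str
    species: str
    age_class: str
    sex: str = "unknown"

    def __post_init__(self) -> None:
        self.species = self.species.strip().lower()
        self.age_class = self.age_class.strip().lower()
        self.sex = self.sex.strip().lower()
        if self.age_class not in AGE_CLASSES:
            raise ValueError(
                f"specimen {self.specimen_id!r}: age_class {self.age_class!r} "
                f"not in {AGE_CLASSES}"
            )
        if self.sex not in SEXES:
            raise ValueError(f"specimen {self.specimen_id!r}: sex {self.sex!r} not in {SEXES}")


@dataclass
class LandmarkDataset:
    """Configurations + metadata + sliders, aligned by specimen_id."""

    configurations: list[LandmarkConfiguration]
    metadata: list[SpecimenMetadata]
    sliders: SliderTable
    group_sizes: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def n(self) -> int:
        return len(self.configurations)

    def coords(self) -> np.ndarray:
        """Stack all configurations into an (n, k, 2) array."""
        return np.stack([c.points for c in self.configurations])

    def species_labels(self) -> np.ndarray:
        return np.array([m.species for m in self.metadata])

    def age_labels(self) -> np.ndarray:
        return np.array([m.age_class for m in self.metadata])


_KEYWORD_RE = re.compile(r"^([A-Za-z]+)\s*=\s*(.*)$")
_REJECTED_KEYWORDS = {"CURVES", "POINTS", "OUTLINES", "RADII"}


def read_tps(path: str | Path, flip_y: bool = False) -> list[LandmarkConfiguration]:
    """Parse a TPS landmark file into configurations, in file order.

    Parameters
    ----------
    path
        TPS file with one or more ``LM=`` records.
    flip_y
        Negate y coordinates (for data digitized in screen convention, where
        y increases downward).  Default keeps stored values.

    Records missing an ``ID=`` line get the 1-based record index as id.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_idx = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KEYWORD_RE.match(line)
        if not m or m.group(1).upper() != "LM":
            raise TPSParseError(f"{path}:{i + 1}: expected LM=<n>, got {line!r}")
        try:
            n_pts = int(m.group(2))
        except ValueError:
            raise TPSParseError(f"{path}:{i + 1}: bad LM count {m.group(2)!r}") from None
        record_idx += 1
        i += 1
        pts = []
        while i < len(lines) and len(pts) < n_pts:
            raw = lines[i].strip()
            i += 1
            if not raw:
                continue
            if _KEYWORD_RE.match(raw):
                break
            fields = raw.split()
            if len(fields) != 2:
                raise TPSParseError(
                    f"{path}:{i}: record {record_idx}: expected 2 coordinates, "
                    f"got {len(fields)}"
                )
            try:
                pts.append((float(fields[0]), float(fields[1])))
            except ValueError:
                raise TPSParseError(
                    f"{path}:{i}: record {record_idx}: non-numeric coordinate {raw!r}"
                ) from None
        if len(pts) != n_pts:
            raise TPSParseError(
                f"{path}: record {record_idx}: LM={n_pts} but found {len(pts)} "
                "coordinate lines"
            )
        image_name = None
        spec_id = None
        scale = None
        while i < len(lines):
            raw = lines[i].strip()
            if not raw:
                i += 1
                continue
            km = _KEYWORD_RE.match(raw)
            if not km:
                raise TPSParseError(f"{path}:{i + 1}: unexpected line {raw!r}")
            key = km.group(1).upper()
            if key == "LM":
                break
            if key in _REJECTED_KEYWORDS:
                raise TPSParseError(
                    f"{path}:{i + 1}: unsupported TPS keyword {key}= "
                    "(outline/curve dialect not handled)"
                )
            if key == "IMAGE":
                image_name = km.group(2)
            elif key == "ID":
                spec_id = km.group(2)
            elif key == "SCALE":
                scale = float(km.group(2))
            else:
                raise TPSParseError(f"{path}:{i + 1}: unknown TPS keyword {key}=")
            i += 1
        points = np.asarray(pts, dtype=float)
        if flip_y:
            points[:, 1] = -points[:, 1]
        configs.append(
            LandmarkConfiguration(
                specimen_id=spec_id if spec_id is not None else str(record_idx),
                points=points,
                image_name=image_name,
                scale=scale,
            )
        )
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise TPSParseError(f"{path}: mixed landmark counts across records: {sorted(ks)}")
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations as a TPS file with 6-decimal fixed-point coordinates."""
    if not configs:
        raise ValueError("cannot write an empty configuration sequence")
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise ValueError(f"mixed landmark counts across configurations: {sorted(ks)}")
    out = []
    for c in configs:
        out.append(f"LM={c.k}")
        for x, y in c.points:
            out.append(f"{x:.6f} {y:.6f}")
        if c.image_name is not None:
            out.append(f"IMAGE={c.image_name}")
        out.append(f"ID={c.specimen_id}")
        if c.scale is not None:
            out.append(f"SCALE={c.scale:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_sliders(path: str | Path, k: int | None = None) -> SliderTable:
    """Read a slider file into a 0-based :class:`SliderTable`.

    Accepts plain three-integer-per-line text (``#`` comments allowed) or the
    tpsUtil sliders dialect, whose header/ID lines are ignored.  In-file
    indices are auto-detected as 1-based if any index equals ``k`` and none
    equals 0; otherwise they are taken as 0-based.  Detection is logged.
    """
    path = Path(path)
    triplets = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _KEYWORD_RE.match(line)
        if m:  # tpsUtil dialect header lines (edgelist=, ID=, ...)
            continue
        fields = line.replace(",", " ").split()
        if len(fields) != 3:
            raise TPSParseError(f"{path}:{lineno}: expected 3 indices, got {len(fields)}")
        try:
            triplets.append(tuple(int(f) for f in fields))
        except ValueError:
            raise TPSParseError(f"{path}:{lineno}: non-integer index in {line!r}") from None
    arr = np.asarray(triplets, dtype=int).reshape(-1, 3)
    one_based = False
    if arr.size:
        if k is not None:
            one_based = arr.max() == k and arr.min() >= 1
        else:
            one_based = arr.min() >= 1
    if one_based:
        arr = arr - 1
        logger.info("slider file %s detected as 1-based; normalized to 0-based", path)
    else:
        logger.info("slider file %s taken as 0-based", path)
    table = SliderTable(arr)
    if k is not None:
        table.validate_for_k(k)
    return table


def write_sliders(table: SliderTable, path: str | Path) -> None:
    lines = ["# before slider after (0-based)"]
    lines += [f"{b} {s} {a}" for b, s, a in table.triplets]
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> list[SpecimenMetadata]:
    """Read a specimen metadata CSV with header specimen_id,species,age_class,sex."""
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"specimen_id", "species", "age_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata {path}: missing columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            SpecimenMetadata(
                specimen_id=str(r["specimen_id"]).strip(),
                species=r["species"],
                age_class=r["age_class"],
                sex=r.get("sex", "unknown") if pd.notna(r.get("sex", "unknown")) else "unknown",
            )
        )
    return rows


def write_metadata(metadata: Sequence[SpecimenMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "specimen_id": m.specimen_id,
                "species": m.species,
                "age_class": m.age_class,
                "sex": m.sex,
            }
            for m in metadata
        ]
    ).to_csv(path, index=False)


def validate_dataset(dataset: LandmarkDataset) -> LandmarkDataset:
    """Assert all dataset invariants; collect and report every violation.

    On success the dataset is returned annotated with group sizes per
    (species, age_class) cell.
    """
    errors: list[str] = []
    configs, meta = dataset.configurations, dataset.metadata

    ks = {c.k for c in configs}
    if len(ks) > 1:
        errors.append(f"mixed landmark counts across configurations: {sorted(ks)}")

    config_ids = [c.specimen_id for c in configs]
    meta_ids = [m.specimen_id for m in meta]
    for name, ids in (("configuration", config_ids), ("metadata", meta_ids)):
        seen, dups = set(), set()
        for sid in ids:
            (dups if sid in seen else seen).add(sid)
        if dups:
            errors.append(f"duplicate {name} specimen_ids: {sorted(dups)}")
    missing_meta = set(config_ids) - set(meta_ids)
    if missing_meta:
        errors.append(f"configurations without metadata: {sorted(missing_meta)}")
    extra_meta = set(meta_ids) - set(config_ids)
    if extra_meta:
        errors.append(f"metadata without configurations: {sorted(extra_meta)}")
    if config_ids != meta_ids and not (missing_meta or extra_meta):
        errors.append("configuration and metadata order differ (ids match as sets)")

    if len(ks) == 1:
        try:
            dataset.sliders.validate_for_k(dataset.k)
        except ValueError as e:
            errors.append(str(e))

    if errors:
        raise DatasetValidationError(errors)

    sizes: dict[tuple[str, str], int] = {}
    for m in meta:
        key = (m.species, m.age_class)
        sizes[key] = sizes.get(key, 0) + 1
    dataset.group_sizes = sizes
    return dataset


def assemble_dataset(
    configurations: Iterable[LandmarkConfiguration],
    metadata: Iterable[SpecimenMetadata],
    sliders: SliderTable,
) -> LandmarkDataset:
    """Order metadata to match configurations and validate the result."""
    configurations = list(configurations)
    by_id = {m.specimen_id: m for m in metadata}
    ordered = [by_id[c.specimen_id] for c in configurations if c.specimen_id in by_id]
    leftover = [m for m in by_id.values() if m not in ordered]
    return validate_dataset(LandmarkDataset(configurations, ordered + leftover, sliders))
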