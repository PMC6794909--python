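"""Reading, validating, subsetting and writing landmark datasets.

Supports the two de-facto community landmark formats (TPS ``LM3=`` blocks and
rectangular NTS matrices) plus a long-format CSV
(``specimen_id, bone_id, landmark_id, x, y, z``) and a specimen metadata CSV.
Coordinate files are unit-agnostic: superimposition removes scale, so units
are carried as metadata only.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("donkey", "horse", "hybrid")
HYBRID_CLASSES = ("mule", "hinny")
SEXES = ("female", "male", "gelding")

#: The sixteen principal limb bones of the equid appendicular skeleton.
BONES = (
    "scapula",
    "humerus",
    "radioulna",
    "metacarpal",
    "prox_phal_ant",
    "mid_phal_ant",
    "dist_phal_ant",
    "coxal",
    "femur",
    "tibia",
    "talus",
    "calcaneus",
    "metatarsal",
    "prox_phal_post",
    "mid_phal_post",
    "dist_phal_post",
)


class ParseError(ValueError):
    """Malformed landmark or metadata file; message names the offending line/row."""


class ValidationError(ValueError):
    """Dataset violates a structural invariant."""


@dataclasses.dataclass
class LandmarkConfiguration:
    """Ordered 3D landmarks of one bone of one specimen."""

    specimen_id: str
    bone_id: str
    coords: np.ndarray  # (k, 3)
    landmark_ids: tuple[str, ...] = ()
    reflect: bool = False  # mirror the first axis before analysis (antimeres)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(
                f"{self.specimen_id}/{self.bone_id}: coords must be (k, 3)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(
                f"{self.specimen_id}/{self.bone_id}: non-finite coordinates"
            )
        if not self.landmark_ids:
            self.landmark_ids = tuple(f"L{i + 1}" for i in range(self.k))
        if len(self.landmark_ids) != self.k:
            raise ValidationError(
                f"{self.specimen_id}/{self.bone_id}: {len(self.landmark_ids)} "
                f"landmark ids for {self.k} landmarks"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def oriented_coords(self) -> np.ndarray:
        """Coordinates with the reflect flag applied (first axis mirrored)."""
        if not self.reflect:
            return self.coords
        out = self.coords.copy()
        out[:, 0] *= -1.0
        return out

    def subset(self, keep: Sequence[str]) -> "LandmarkConfiguration":
        index = {lid: i for i, lid in enumerate(self.landmark_ids)}
        rows = [index[lid] for lid in keep]
        return LandmarkConfiguration(
            self.specimen_id,
            self.bone_id,
            self.coords[rows],
            tuple(keep),
            self.reflect,
        )


@dataclasses.dataclass
class SpecimenRecord:
    specimen_id: str
    group: str  # donkey | horse | hybrid
    hybrid_class: str | None = None  # mule | hinny, only when group == hybrid
    sex: str | None = None  # female | male | gelding
    breed: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"specimen {self.specimen_id}: unknown group {self.group!r}"
            )
        if self.hybrid_class is not None and self.group != "hybrid":
            raise ValidationError(
                f"specimen {self.specimen_id}: hybrid_class set but group is "
                f"{self.group!r}"
            )
        if self.hybrid_class is not None and self.hybrid_class not in HYBRID_CLASSES:
            raise ValidationError(
                f"specimen {self.specimen_id}: unknown hybrid_class "
                f"{self.hybrid_class!r}"
            )
        if self.sex is not None and self.sex not in SEXES:
            raise ValidationError(
                f"specimen {self.specimen_id}: unknown sex {self.sex!r}"
            )


@dataclasses.dataclass
class StudyDataset:
    """Specimens x bones with group/sex/breed labels; the unit the pipeline runs on."""

    specimens: list[SpecimenRecord]
    configurations: dict[tuple[str, str], LandmarkConfiguration]
    exclusion_lists: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    pooled_hybrids: bool = True

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        known = {s.specimen_id for s in self.specimens}
        if len(known) != len(self.specimens):
            raise ValidationError("duplicate specimen ids in metadata")
        per_bone: dict[str, tuple[str, ...]] = {}
        for (sid, bid), cfg in self.configurations.items():
            if sid not in known:
                raise ValidationError(f"configuration for unknown specimen {sid!r}")
            if (cfg.specimen_id, cfg.bone_id) != (sid, bid):
                raise ValidationError(f"configuration key/content mismatch for {sid}/{bid}")
            ref = per_bone.setdefault(bid, cfg.landmark_ids)
            if cfg.landmark_ids != ref:
                raise ValidationError(
                    f"bone {bid!r}: landmark set of specimen {sid!r} differs "
                    "from the rest of the sample"
                )

    @property
    def bones(self) -> list[str]:
        return sorted({bid for (_, bid) in self.configurations})

    def record(self, specimen_id: str) -> SpecimenRecord:
        for s in self.specimens:
            if s.specimen_id == specimen_id:
                return s
        raise KeyError(specimen_id)

    def configurations_for_bone(self, bone_id: str) -> list[LandmarkConfiguration]:
        return [
            cfg
            for (sid, bid), cfg in sorted(self.configurations.items())
            if bid == bone_id
        ]

    def analysis_label(self, record: SpecimenRecord) -> str:
        """Group label used in analyses.

        With pooled hybrids (the default, motivated by small hybrid samples)
        mules and hinnies share the single label ``hybrid``; unpooled, each
        hybrid class is its own stratum. ``hybrid_class`` is always retained
        for reporting.
        """
        if record.group == "hybrid" and not self.pooled_hybrids:
            return record.hybrid_class or "hybrid"
        return record.group

    def labels_for_bone(self, bone_id: str) -> np.ndarray:
        return np.array(
            [
                self.analysis_label(self.record(cfg.specimen_id))
                for cfg in self.configurations_for_bone(bone_id)
            ]
        )

    def _replace(self, **kw) -> "StudyDataset":
        return StudyDataset(
            specimens=kw.get("specimens", self.specimens),
            configurations=kw.get("configurations", self.configurations),
            exclusion_lists=kw.get("exclusion_lists", self.exclusion_lists),
            pooled_hybrids=kw.get("pooled_hybrids", self.pooled_hybrids),
        )


def apply_exclusions(dataset: StudyDataset) -> StudyDataset:
    """Drop the excluded landmarks of each bone (fragmentary-bone handling).

    Idempotent: excluded ids are removed from the configurations and the
    exclusion lists are cleared. At least four landmarks must survive on each
    bone for a 3D analysis.
    """
    if not dataset.exclusion_lists:
        return dataset
    configs: dict[tuple[str, str], LandmarkConfiguration] = {}
    for key, cfg in dataset.configurations.items():
        excluded = dataset.exclusion_lists.get(cfg.bone_id, [])
        if not excluded:
            configs[key] = cfg
            continue
        unknown = set(excluded) - set(cfg.landmark_ids)
        if unknown:
            raise ValidationError(
                f"bone {cfg.bone_id!r}: excluded landmarks {sorted(unknown)} do not exist"
            )
        keep = [lid for lid in cfg.landmark_ids if lid not in excluded]
        if len(keep) < 4:
            raise ValidationError(
                f"bone {cfg.bone_id!r}: exclusions leave only {len(keep)} "
                "landmarks (minimum 4 for 3D analysis)"
            )
        configs[key] = cfg.subset(keep)
    return dataset._replace(configurations=configs, exclusion_lists={})


def pool_hybrids(dataset: StudyDataset, pool: bool = True) -> StudyDataset:
    """Choose whether mules and hinnies are analysed as one ``hybrid`` group."""
    return dataset._replace(pooled_hybrids=pool)


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

def read_tps(path: str | Path, bone_id: str = "bone") -> list[LandmarkConfiguration]:
    """Read a TPS file with ``LM3=k`` blocks and optional ``ID=`` lines."""
    path = Path(path)
    configs: list[LandmarkConfiguration] = []
    lines = path.read_text().splitlines()
    i, n_block = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM3="):
            raise ParseError(f"{path}:{i + 1}: expected 'LM3=' block, got {line!r}")
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{i + 1}: bad landmark count {line!r}") from exc
        coords = np.empty((k, 3))
        for j in range(k):
            i += 1
            if i >= len(lines):
                raise ParseError(f"{path}: truncated block starting near line {i - j}")
            parts = lines[i].split()
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{i + 1}: expected 3 coordinates, got {len(parts)}"
                )
            try:
                coords[j] = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(f"{path}:{i + 1}: non-numeric coordinate") from exc
        n_block += 1
        specimen_id = f"spec{n_block}"
        i += 1
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM3="):
            key, value = lines[i].strip().split("=", 1)
            if key.upper() == "ID":
                specimen_id = value.strip()
            i += 1
        configs.append(LandmarkConfiguration(specimen_id, bone_id, coords))
    _check_common_k(configs, path)
    return configs


def write_tps(configs: Iterable[LandmarkConfiguration], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cfg in configs:
            fh.write(f"LM3={cfg.k}\n")
            for row in cfg.coords:
                fh.write(f"{row[0]:.17g} {row[1]:.17g} {row[2]:.17g}\n")
            fh.write(f"ID={cfg.specimen_id}\n")


# ---------------------------------------------------------------------------
# NTS
# ---------------------------------------------------------------------------

def read_nts(path: str | Path, bone_id: str = "bone") -> list[LandmarkConfiguration]:
    """Read a rectangular NTS matrix (header ``1 nL 3k 0 dim=3``)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith('"')]
    header = lines[0].split()
    if len(header) < 4:
        raise ParseError(f"{path}:1: malformed NTS header {lines[0]!r}")
    labelled = header[1].upper().endswith("L")
    try:
        n = int(header[1].rstrip("Ll"))
        ncol = int(header[2])
    except ValueError as exc:
        raise ParseError(f"{path}:1: malformed NTS header {lines[0]!r}") from exc
    dim = 3
    for tok in header[4:]:
        if tok.lower().startswith("dim="):
            dim = int(tok.split("=")[1])
    if dim != 3 or ncol % 3:
        raise ParseError(f"{path}: only 3D NTS matrices are supported")
    k = ncol // 3
    body = lines[1:]
    if labelled:
        labels: list[str] = []
        while len(labels) < n:
            labels.extend(body.pop(0).split())
        if len(labels) != n:
            raise ParseError(f"{path}: expected {n} row labels, found {len(labels)}")
    else:
        labels = [f"spec{i + 1}" for i in range(n)]
    values: list[float] = []
    for offset, ln in enumerate(body):
        for tok in ln.split():
            try:
                values.append(float(tok))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric value {tok!r} in matrix body"
                ) from exc
    if len(values) != n * ncol:
        raise ParseError(
            f"{path}: expected {n * ncol} values, found {len(values)}"
        )
    data = np.array(values).reshape(n, k, 3)
    return [
        LandmarkConfiguration(labels[i], bone_id, data[i]) for i in range(n)
    ]


def write_nts(configs: Sequence[LandmarkConfiguration], path: str | Path) -> None:
    configs = list(configs)
    _check_common_k(configs, path)
    k = configs[0].k
    with open(path, "w") as fh:
        fh.write(f"1 {len(configs)}L {3 * k} 0 dim=3\n")
        fh.write(" ".join(c.specimen_id for c in configs) + "\n")
        for cfg in configs:
            fh.write(" ".join(f"{v:.17g}" for v in cfg.coords.ravel()) + "\n")


# ---------------------------------------------------------------------------
# CSV (long format) and metadata
# ---------------------------------------------------------------------------

def read_landmarks_csv(path: str | Path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(
        path,
        dtype={"specimen_id": str, "bone_id": str, "landmark_id": str},
        float_precision="round_trip",
    )
    required = {"specimen_id", "bone_id", "landmark_id", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x", "y", "z"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(np.argmax(coerced.isna().to_numpy()))
            raise ParseError(
                f"{path}: non-numeric {col!r} value at data row {row + 1}"
            )
        df[col] = coerced
        del bad
    configs = []
    for (sid, bid), grp in df.groupby(["specimen_id", "bone_id"], sort=True):
        configs.append(
            LandmarkConfiguration(
                str(sid),
                str(bid),
                grp[["x", "y", "z"]].to_numpy(dtype=float),
                tuple(grp["landmark_id"].astype(str)),
            )
        )
    return configs


def write_landmarks_csv(configs: Iterable[LandmarkConfiguration], path: str | Path) -> None:
    rows = []
    for cfg in configs:
        for lid, (x, y, z) in zip(cfg.landmark_ids, cfg.coords):
            rows.append((cfg.specimen_id, cfg.bone_id, lid, x, y, z))
    pd.DataFrame(
        rows, columns=["specimen_id", "bone_id", "landmark_id", "x", "y", "z"]
    ).to_csv(path, index=False, float_format="%.17g")


def read_landmarks(path: str | Path, format: str, bone_id: str = "bone") -> list[LandmarkConfiguration]:
    """Dispatch on format name: ``tps`` | ``nts`` | ``csv``."""
    if format == "tps":
        return read_tps(path, bone_id)
    if format == "nts":
        return read_nts(path, bone_id)
    if format == "csv":
        return read_landmarks_csv(path)
    raise ValueError(f"unknown landmark format {format!r}")


def read_metadata_csv(path: str | Path) -> list[SpecimenRecord]:
    df = pd.read_csv(path, dtype=str)
    if "specimen_id" not in df.columns or "group" not in df.columns:
        raise ParseError(f"{path}: metadata needs at least specimen_id and group")
    records = []
    for _, row in df.iterrows():
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                group=str(row["group"]),
                hybrid_class=_opt(row.get("hybrid_class")),
                sex=_opt(row.get("sex")),
                breed=_opt(row.get("breed")),
            )
        )
    return records


def write_metadata_csv(specimens: Iterable[SpecimenRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.specimen_id, s.group, s.hybrid_class, s.sex, s.breed)
            for s in specimens
        ],
        columns=["specimen_id", "group", "hybrid_class", "sex", "breed"],
    ).to_csv(path, index=False)


def write_study(dataset: StudyDataset, directory: str | Path) -> None:
    """Write a StudyDataset as one long-format landmark CSV plus metadata CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_landmarks_csv(
        (cfg for _, cfg in sorted(dataset.configurations.items())),
        directory / "landmarks.csv",
    )
    write_metadata_csv(dataset.specimens, directory / "specimens.csv")


def read_study(directory: str | Path, exclusion_lists: Mapping[str, list[str]] | None = None) -> StudyDataset:
    directory = Path(directory)
    configs = read_landmarks_csv(directory / "landmarks.csv")
    specimens = read_metadata_csv(directory / "specimens.csv")
    return StudyDataset(
        specimens=specimens,
        configurations={(c.specimen_id, c.bone_id): c for c in configs},
        exclusion_lists=dict(exclusion_lists or {}),
    )


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    value = str(value).strip()
    return value or None


def _check_common_k(configs: Sequence[LandmarkConfiguration], path) -> None:
    ks = {c.k for c in configs}
    if len(ks) > 1:
        raise ValidationError(
            f"{path}: ragged landmark counts within one bone: {sorted(ks)}"
        )
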