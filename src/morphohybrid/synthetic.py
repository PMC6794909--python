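"""Synthetic study generator with recorded ground truth.

Emulates the statistical structure the analysis pipeline assumes: two parent
species (donkey, horse) whose per-bone mean shapes diverge along a fixed
direction of shape space, F1 hybrids (mules and hinnies) placed at a
controllable position relative to the parents — a fraction ``f`` along the
inter-parent axis plus an orthogonal transgressive offset ``t`` (both in
units of the parent separation) — within-group tangent-space noise,
group-specific log-normal size distributions with per-bone allometric
slopes, optional sex effects (optionally species-specific, to induce a
species x sex interaction), and inter-bone integration planted as shared
latent factors on designated loading directions.

All planted directions and the noise live in the orthogonal complement of
the similarity subspace at the base shape, so generalized Procrustes
superimposition neither absorbs nor distorts them and the closed-form index
expectations recorded in :class:`SyntheticTruth` remain valid. Each emitted
configuration is then randomly rotated, translated and scaled (to its drawn
centroid size), so superimposition has real work to do.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .geometry import centroid_size, random_rotation, similarity_basis
from .io import LandmarkConfiguration, SpecimenRecord, StudyDataset

__all__ = ["GeneratorSpec", "SyntheticTruth", "generate_study", "truth_report"]

#: landmark counts per bone used by the default study (trimmed digitization
#: protocols: more landmarks on long bones than on short autopodial elements)
DEFAULT_BONES: dict[str, int] = {
    "scapula": 10,
    "humerus": 12,
    "radioulna": 12,
    "metacarpal": 10,
    "prox_phal_ant": 8,
    "mid_phal_ant": 8,
    "dist_phal_ant": 8,
    "coxal": 10,
    "femur": 12,
    "tibia": 12,
    "talus": 8,
    "calcaneus": 8,
    "metatarsal": 10,
    "prox_phal_post": 8,
    "mid_phal_post": 8,
    "dist_phal_post": 8,
}


@dataclasses.dataclass
class GeneratorSpec:
    """Parameters of one synthetic study; defaults mirror the reference
    sample of 42 horses, 38 donkeys and 21 hybrids (13 mules, 8 hinnies)."""

    n_per_group: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"donkey": 38, "horse": 42, "hybrid": 21}
    )
    n_mules: int = 13
    bones: dict[str, int] = dataclasses.field(default_factory=lambda: dict(DEFAULT_BONES))
    #: parent mean-shape separation, in Procrustes (tangent) units
    divergence: float | dict[str, float] = 0.1
    #: hybrid placement per bone: fraction f along the donkey->horse axis and
    #: orthogonal transgressive offset t, both as fractions of the separation
    hybrid_placement: tuple[float, float] | dict[str, tuple[float, float]] = (0.45, 0.4)
    #: within-group tangent noise sd per shape dimension. The plug-in
    #: Euclidean distance between two estimated group means of size n carries
    #: a noise-floor bias ~ sqrt(2 p sigma^2 / n) (p shape dimensions); the
    #: default keeps that floor ~1% of the parent separation at n = 200 so
    #: index recovery sits in its asymptotic regime
    noise_sd: float | dict[str, float] = 0.00125
    #: planted inter-bone integration: (bone_a, bone_b, rho) with rho the
    #: cross-block correlation on one loading direction per bone
    integration: list[tuple[str, str, float]] = dataclasses.field(default_factory=list)
    #: sd multiplier of the shared-factor loading direction relative to
    #: noise_sd. Within-group variation of real bones is anisotropic: the
    #: covarying factor carries a dominant variance share rather than 1/p of
    #: the total, which is what makes empirical rPLS separable from its
    #: permutation null even at modest n.
    integration_factor_scale: float = 3.0
    #: allometric slope magnitude (tangent units per log10 size unit); a
    #: mapping group -> magnitude breaks slope homogeneity. The default puts
    #: ~10% of within-group shape variance on size, the weak-allometry
    #: regime of adult limb bones
    allometry: float | dict[str, float] = 0.02
    #: per-group mean and sd of log10 centroid size
    size_distributions: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {
            "donkey": (2.20, 0.06),
            "horse": (2.35, 0.10),
            "hybrid": (2.30, 0.07),
        }
    )
    #: optional sex effect: bone -> (magnitude, species-or-None); applied to
    #: males, restricted to one species when given (inducing an interaction)
    sex_effect: dict[str, tuple[float, str | None]] = dataclasses.field(default_factory=dict)
    sex_probs: tuple[float, float, float] = (0.48, 0.47, 0.05)  # female, male, gelding
    missing_rate: float = 0.0  # per-configuration drop probability (sub-complete skeletons)
    seed: int = 0

    def placement(self, bone: str) -> tuple[float, float]:
        if isinstance(self.hybrid_placement, dict):
            return tuple(self.hybrid_placement[bone])
        return tuple(self.hybrid_placement)

    def _per_bone(self, value, bone: str) -> float:
        return float(value[bone]) if isinstance(value, dict) else float(value)

    def divergence_of(self, bone: str) -> float:
        return self._per_bone(self.divergence, bone)

    def noise_of(self, bone: str) -> float:
        return self._per_bone(self.noise_sd, bone)

    def allometry_of(self, group: str) -> float:
        if isinstance(self.allometry, dict):
            return float(self.allometry.get(group, 0.0))
        return float(self.allometry)


def expected_indices(f: float, t: float) -> tuple[float, float]:
    """Closed-form transgression and dominance for a hybrid at (f, t)."""
    m1 = np.hypot(f, t)          # donkey-hybrid distance / separation
    m2 = np.hypot(1.0 - f, t)    # horse-hybrid distance / separation
    transgression = (m1 + m2 - 1.0) * 100.0
    dominance = (m2 - m1) / (m1 + m2) * 100.0
    return float(transgression), float(dominance)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth recoverable from a generated study."""

    expected_transgression: dict[str, float]
    expected_dominance: dict[str, float]
    planted_edges: list[tuple[str, str, float]]
    generating_slopes: dict[str, dict[str, float]]  # bone -> group -> magnitude
    divergence: dict[str, float]
    placement: dict[str, tuple[float, float]]
    noise_sd: dict[str, float]
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def truth_report(spec: GeneratorSpec) -> SyntheticTruth:
    """Closed-form expectations and planted structure, for use as oracles."""
    groups = sorted(spec.n_per_group)
    trans, dom, slopes, div, place, noise = {}, {}, {}, {}, {}, {}
    for bone in spec.bones:
        f, t = spec.placement(bone)
        trans[bone], dom[bone] = expected_indices(f, t)
        slopes[bone] = {g: spec.allometry_of(g) for g in groups}
        div[bone] = spec.divergence_of(bone)
        place[bone] = (f, t)
        noise[bone] = spec.noise_of(bone)
    return SyntheticTruth(
        expected_transgression=trans,
        expected_dominance=dom,
        planted_edges=[(a, b, r) for a, b, r in spec.integration if r > 0],
        generating_slopes=slopes,
        divergence=div,
        placement=place,
        noise_sd=noise,
        seed=spec.seed,
    )


def _base_shape(k: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic (given the stream) non-degenerate base configuration:
    a stretched helix with jitter, giving well-separated principal moments."""
    t = np.linspace(0.0, 1.0, k)
    base = np.column_stack(
        [
            np.cos(2 * np.pi * t) * (1.0 + 0.2 * np.sin(5 * t)),
            0.7 * np.sin(2 * np.pi * t),
            2.2 * (t - 0.5),
        ]
    )
    base = base + 0.05 * rng.standard_normal((k, 3))
    base -= base.mean(axis=0)
    return base / np.sqrt((base**2).sum())


def _orthonormal_directions(basis: np.ndarray, n_dirs: int, rng: np.random.Generator) -> np.ndarray:
    k3 = basis.shape[1]
    if n_dirs > k3 - basis.shape[0]:
        raise ValueError(
            f"bone has only {k3 - basis.shape[0]} shape dimensions but the "
            f"requested structure needs {n_dirs}; increase the landmark count"
        )
    stack = basis.copy()
    dirs = []
    while len(dirs) < n_dirs:
        v = rng.standard_normal(k3)
        v -= (stack @ v) @ stack
        norm = np.linalg.norm(v)
        if norm < 1e-8:
            continue
        v /= norm
        dirs.append(v)
        stack = np.vstack([stack, v])
    return np.array(dirs)


def generate_study(spec: GeneratorSpec) -> tuple[StudyDataset, SyntheticTruth]:
    """Draw one study; bit-reproducible given ``spec.seed``."""
    for bone, k in spec.bones.items():
        if 3 * k - 7 < 4 + sum(1 for a, b, _ in spec.integration if bone in (a, b)):
            raise ValueError(f"bone {bone!r}: k={k} too small for requested structure")
    ss = np.random.SeedSequence(spec.seed)
    meta_rng, latent_rng, *bone_seeds = [
        np.random.default_rng(s) for s in ss.spawn(2 + len(spec.bones))
    ]

    groups = sorted(spec.n_per_group)
    specimens: list[SpecimenRecord] = []
    prefix = {"donkey": "don", "horse": "hor", "hybrid": "hyb"}
    for g in groups:
        n_g = spec.n_per_group[g]
        sexes = meta_rng.choice(
            ["female", "male", "gelding"], size=n_g, p=np.asarray(spec.sex_probs) / sum(spec.sex_probs)
        )
        for i in range(n_g):
            hybrid_class = None
            if g == "hybrid":
                hybrid_class = "mule" if i < spec.n_mules else "hinny"
            specimens.append(
                SpecimenRecord(
                    specimen_id=f"{prefix.get(g, g[:3])}{i + 1:03d}",
                    group=g if g in ("donkey", "horse", "hybrid") else g,
                    hybrid_class=hybrid_class,
                    sex=str(sexes[i]),
                )
            )
    n_total = len(specimens)
    group_of = np.array([s.group for s in specimens])
    sex_of = np.array([s.sex for s in specimens])
    size_deviate = meta_rng.standard_normal(n_total)  # shared across bones

    # one latent per planted edge per specimen, shared by both member bones
    latents = {
        (a, b): latent_rng.standard_normal(n_total) for a, b, _ in spec.integration
    }

    configurations: dict[tuple[str, str], LandmarkConfiguration] = {}
    for (bone, k), rng in zip(spec.bones.items(), bone_seeds):
        base = _base_shape(k, rng)
        basis = similarity_basis(base)
        edges = [(a, b, r) for a, b, r in spec.integration if bone in (a, b)]
        n_dirs = 4 + len(edges)  # u, v, allometry, sex, loadings
        dirs = _orthonormal_directions(basis, n_dirs, rng)
        u, v, w_allo, w_sex = dirs[0], dirs[1], dirs[2], dirs[3]
        loadings = {(a, b): dirs[4 + i] for i, (a, b, _) in enumerate(edges)}

        d = spec.divergence_of(bone)
        f, t = spec.placement(bone)
        sigma = spec.noise_of(bone)
        flat_base = base.ravel()
        means = {
            "donkey": flat_base - 0.5 * d * u,
            "horse": flat_base + 0.5 * d * u,
        }
        means["hybrid"] = means["donkey"] + f * d * u + t * d * v
        for g in groups:
            means.setdefault(g, flat_base)

        mu_sd = spec.size_distributions
        log_sizes = np.array(
            [
                mu_sd[g][0] + mu_sd[g][1] * size_deviate[i]
                for i, g in enumerate(group_of)
            ]
        )
        sex_cfg = spec.sex_effect.get(bone)

        noise = sigma * rng.standard_normal((n_total, 3 * k))
        # restrict noise to the shape (similarity-complement) subspace
        noise -= (noise @ basis.T) @ basis
        for (a, b, rho) in edges:
            w = loadings[(a, b)]
            c = noise @ w  # current iid coefficient, sd sigma
            mixed = spec.integration_factor_scale * sigma * (
                np.sqrt(rho) * latents[(a, b)] + np.sqrt(1.0 - rho) * (c / sigma)
            )
            noise += np.outer(mixed - c, w)

        for i, record in enumerate(specimens):
            if spec.missing_rate > 0 and rng.random() < spec.missing_rate:
                continue
            g = record.group
            dev = noise[i].copy()
            dev += spec.allometry_of(g) * (log_sizes[i] - mu_sd[g][0]) * w_allo
            if sex_cfg is not None:
                magnitude, species = sex_cfg
                if sex_of[i] == "male" and (species is None or g == species):
                    dev += magnitude * w_sex
            coords = (means[g] + dev).reshape(k, 3)
            # random similarity transform: GPA must undo it
            size = 10.0 ** log_sizes[i]
            coords = coords - coords.mean(axis=0)
            coords = coords / centroid_size(coords) * size
            coords = coords @ random_rotation(rng).T
            coords = coords + size * rng.standard_normal(3)
            configurations[(record.specimen_id, bone)] = LandmarkConfiguration(
                record.specimen_id, bone, coords
            )

    dataset = StudyDataset(
        specimens=specimens, configurations=configurations, pooled_hybrids=True
    )
    return dataset, truth_report(spec)
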