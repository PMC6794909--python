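"""Config-driven orchestration of the full analysis sequence.

Per bone: GPA -> PCA (with scatter data) -> pairwise MANOVA on the PCs
explaining the retention threshold of variance -> two-way species x sex
MANOVA with automatic sex-stratified reanalysis of bones showing a
significant interaction -> disparity (Procrustes variances with permutation
pairwise comparisons) -> size ANOVA -> allometry (shape~log10 size
regression and RRPP slope-homogeneity test) -> transgression/dominance
table; then the two-block PLS covariation network per group over the
configured bone-pair sets and the between-group z-score comparison table.
A machine-readable manifest records the seed, permutation counts and
configuration hash; with a fixed seed the whole report bundle is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import allometry as allom
from .hybrid_indices import hybrid_indices, hybrid_indices_with_uncertainty
from . import integration as integ
from . import shape_stats as stats_mod
from .io import StudyDataset, apply_exclusions, pool_hybrids, read_study
from .procrustes import gpa
from .synthetic import GeneratorSpec, generate_study

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and bone."""


@dataclasses.dataclass
class RunConfig:
    generator: GeneratorSpec | None = None
    input_dir: str | None = None
    exclusions: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    pool_hybrids: bool = True
    pc_threshold: float = 0.90
    n_perm: int = 999
    n_boot: int = 0
    alpha: float = 0.05
    seed: int = 0
    output_dir: str | None = None
    pair_sets: list[integ.BonePairSet] = dataclasses.field(
        default_factory=integ.default_pair_sets
    )

    def __post_init__(self) -> None:
        if not 0 < self.pc_threshold <= 1:
            raise ValueError("pc_threshold must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.generator is None and self.input_dir is None:
            self.generator = GeneratorSpec(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        kw = dict(raw)
        gen = kw.pop("generator", None)
        if gen is not None:
            gen = GeneratorSpec(**{
                k: (
                    {bone: tuple(v) for bone, v in val.items()}
                    if k == "hybrid_placement" and isinstance(val, dict)
                    else tuple(val) if k == "hybrid_placement"
                    else [tuple(e) for e in val] if k == "integration"
                    else {g: tuple(v) for g, v in val.items()} if k == "size_distributions"
                    else {b: tuple(v) for b, v in val.items()} if k == "sex_effect"
                    else val
                )
                for k, val in gen.items()
            })
        sets = kw.pop("pair_sets", None)
        if sets is not None:
            sets = [
                integ.BonePairSet(name, [tuple(p) for p in pairs])
                for name, pairs in sets.items()
            ]
        cfg = cls(generator=gen, **kw)
        if sets is not None:
            cfg.pair_sets = sets
        return cfg

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)  # where the bundle lands is not part of the analysis
        blob = json.dumps(_jsonable(payload), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _stage_streams(seed: int, bones: list[str]) -> dict[tuple[str, str], np.random.Generator]:
    """One deterministic RNG stream per (bone, stage), plus study-level stages."""
    stages = ("disparity", "regression", "slopes", "bootstrap")
    keys = [(b, s) for b in bones for s in stages] + [("", "network")]
    ss = np.random.SeedSequence(seed)
    return {k: np.random.default_rng(c) for k, c in zip(keys, ss.spawn(len(keys)))}


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis; returns the report bundle as a dict of tables
    (pandas DataFrames) plus the manifest, and writes CSV/JSON when
    ``config.output_dir`` is set."""
    if config.input_dir is not None:
        dataset = read_study(config.input_dir, config.exclusions)
        truth = None
    else:
        dataset, truth = generate_study(config.generator)
        if config.exclusions:
            dataset = dataset._replace(exclusion_lists=dict(config.exclusions))
    dataset = apply_exclusions(dataset)
    dataset = pool_hybrids(dataset, config.pool_hybrids)

    bones = dataset.bones
    streams = _stage_streams(config.seed, bones)
    bundle: dict[str, Any] = {}
    tables: dict[str, list] = {
        "pca_scores": [],
        "pca_variance": [],
        "manova_pairwise": [],
        "manova_twoway": [],
        "disparity": [],
        "disparity_pairwise": [],
        "size_anova": [],
        "size_pairwise": [],
        "allometry": [],
        "hybrid_indices": [],
        "hybrid_indices_by_sex": [],
    }
    aligned_by_bone = {}
    stratified_bones: list[str] = []

    for bone in bones:
        configs = dataset.configurations_for_bone(bone)
        labels = dataset.labels_for_bone(bone)
        records = [dataset.record(c.specimen_id) for c in configs]
        sexes = np.array([r.sex or "" for r in records])

        def _stage(name):
            return f"bone {bone!r}, stage {name!r}"

        try:
            aligned = gpa(configs, bone_id=bone)
        except Exception as exc:
            raise PipelineError(f"{_stage('gpa')}: {exc}") from exc
        aligned_by_bone[bone] = aligned
        log_sizes = np.log10(aligned.centroid_sizes)

        try:
            pca_res = stats_mod.pca(aligned.shape_variables)
            retained = stats_mod.retain_pcs(pca_res, config.pc_threshold)
            scores = pca_res.scores[:, retained]
        except Exception as exc:
            raise PipelineError(f"{_stage('pca')}: {exc}") from exc
        for i, cfg in enumerate(configs):
            tables["pca_scores"].append(
                {
                    "bone": bone,
                    "specimen_id": cfg.specimen_id,
                    "group": labels[i],
                    "sex": sexes[i],
                    "pc1": pca_res.scores[i, 0],
                    "pc2": pca_res.scores[i, 1] if pca_res.n_axes > 1 else 0.0,
                }
            )
        tables["pca_variance"].append(
            {
                "bone": bone,
                "n_retained": len(retained),
                "pc1_fraction": pca_res.variance_fractions[0],
                "pc2_fraction": (
                    pca_res.variance_fractions[1] if pca_res.n_axes > 1 else 0.0
                ),
            }
        )

        try:
            pm = stats_mod.pairwise_manova(scores, labels)
            pm.insert(0, "bone", bone)
            tables["manova_pairwise"].extend(pm.to_dict("records"))
        except stats_mod.DegenerateDataError as exc:
            tables["manova_pairwise"].append({"bone": bone, "flag": str(exc)})

        try:
            tw = stats_mod.two_way_manova(scores, labels, sexes)
            tw_row = {"bone": bone, **tw}
        except stats_mod.DegenerateDataError as exc:
            tw_row = {"bone": bone, "flag": str(exc)}
        tables["manova_twoway"].append(tw_row)
        interaction_p = tw_row.get("interaction_p")

        # the sex-stratification rule: a significant species x sex
        # interaction sends the bone to per-sex index computation
        if interaction_p is not None and interaction_p < config.alpha:
            stratified_bones.append(bone)
            for sex in ("female", "male"):
                mask = sexes == sex
                present = set(labels[mask])
                if not {"donkey", "horse", "hybrid"} <= present:
                    continue
                res = hybrid_indices(
                    aligned.shape_variables[mask], labels[mask]
                )
                tables["hybrid_indices_by_sex"].append(
                    {
                        "bone": bone,
                        "sex": sex,
                        "n": int(mask.sum()),
                        "d_donkey_horse": res.d_donkey_horse,
                        "d_donkey_hybrid": res.d_donkey_hybrid,
                        "d_horse_hybrid": res.d_horse_hybrid,
                        "transgression_pct": res.transgression_pct,
                        "dominance_pct": res.dominance_pct,
                    }
                )

        try:
            disp = stats_mod.disparity_pairwise(
                aligned.shape_variables,
                labels,
                n_perm=config.n_perm,
                seed=streams[(bone, "disparity")],
            )
        except Exception as exc:
            raise PipelineError(f"{_stage('disparity')}: {exc}") from exc
        for g, v in disp.variances.items():
            tables["disparity"].append({"bone": bone, "group": g, "procrustes_variance": v})
        for (a, b), p_adj in disp.pairwise_p.items():
            tables["disparity_pairwise"].append(
                {
                    "bone": bone,
                    "group_a": a,
                    "group_b": b,
                    "p_adj": p_adj,
                    "p": disp.pairwise_p_raw[(a, b)],
                    "significant": p_adj < config.alpha,
                }
            )

        try:
            anova, pairwise = allom.size_anova(log_sizes, labels)
        except Exception as exc:
            raise PipelineError(f"{_stage('size_anova')}: {exc}") from exc
        tables["size_anova"].append({"bone": bone, **anova.iloc[0].to_dict()})
        pairwise.insert(0, "bone", bone)
        tables["size_pairwise"].extend(pairwise.to_dict("records"))

        try:
            reg = allom.shape_size_regression(
                aligned.shape_variables,
                log_sizes,
                n_perm=config.n_perm,
                seed=streams[(bone, "regression")],
            )
            hom_p, hom_f, _ = allom.slope_homogeneity(
                aligned.shape_variables,
                log_sizes,
                labels,
                n_perm=config.n_perm,
                seed=streams[(bone, "slopes")],
            )
        except Exception as exc:
            raise PipelineError(f"{_stage('allometry')}: {exc}") from exc
        tables["allometry"].append(
            {
                "bone": bone,
                "r_squared": reg.r_squared,
                "p": reg.p_value,
                "homogeneity_p": hom_p,
                "homogeneity_F": hom_f,
                "slopes_parallel": hom_p >= config.alpha,
            }
        )

        if {"donkey", "horse", "hybrid"} <= set(labels):
            try:
                if config.n_boot >= 100:
                    res = hybrid_indices_with_uncertainty(
                        aligned.shape_variables,
                        labels,
                        n_boot=config.n_boot,
                        seed=streams[(bone, "bootstrap")],
                    )
                else:
                    res = hybrid_indices(aligned.shape_variables, labels)
            except Exception as exc:
                raise PipelineError(f"{_stage('hybrid_indices')}: {exc}") from exc
            row = {
                "bone": bone,
                "d_donkey_horse": res.d_donkey_horse,
                "d_donkey_hybrid": res.d_donkey_hybrid,
                "d_horse_hybrid": res.d_horse_hybrid,
                "transgression_pct": res.transgression_pct,
                "dominance_pct": res.dominance_pct,
            }
            if res.transgression_ci is not None:
                row["transgression_lo"], row["transgression_hi"] = res.transgression_ci
                row["dominance_lo"], row["dominance_hi"] = res.dominance_ci
            tables["hybrid_indices"].append(row)

    # integration network + effect-size comparisons across the study
    try:
        labels_map = {
            s.specimen_id: dataset.analysis_label(s) for s in dataset.specimens
        }
        net_seed = int(streams[("", "network")].integers(2**31 - 1))
        network = integ.covariation_network(
            {b: a.shape_variables for b, a in aligned_by_bone.items()},
            {b: a.specimen_ids for b, a in aligned_by_bone.items()},
            labels_map,
            config.pair_sets,
            n_perm=config.n_perm,
            seed=net_seed,
            alpha=config.alpha,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'integration': {exc}") from exc

    z_rows = []
    if not network.empty:
        by_pair = network.groupby(["bone_a", "bone_b", "pair_set"])
        comparisons = []
        for (a, b, ps), sub in by_pair:
            gs = list(sub["group"])
            for i in range(len(gs)):
                for j in range(i + 1, len(gs)):
                    za, sa = sub.iloc[i]["z"], sub.iloc[i]["z_se"]
                    zb, sb = sub.iloc[j]["z"], sub.iloc[j]["z_se"]
                    stat = abs(za - zb) / np.sqrt(sa**2 + sb**2)
                    from scipy.stats import norm

                    p = min(1.0, 2.0 * float(norm.sf(stat)))
                    comparisons.append(
                        {
                            "bone_a": a,
                            "bone_b": b,
                            "pair_set": ps,
                            "group_a": gs[i],
                            "group_b": gs[j],
                            "z_a": za,
                            "z_b": zb,
                            "stat": stat,
                            "p": p,
                        }
                    )
        m = len(comparisons)
        for row in comparisons:
            row["p_adj"] = min(1.0, row["p"] * m)
            row["significant"] = row["p_adj"] < config.alpha
        z_rows = comparisons

    for name, rows in tables.items():
        bundle[name] = pd.DataFrame(rows)
    bundle["integration_edges"] = network
    bundle["z_comparisons"] = pd.DataFrame(z_rows)
    bundle["stratified_bones"] = stratified_bones
    bundle["manifest"] = {
        "package_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_boot": config.n_boot,
        "pc_threshold": config.pc_threshold,
        "alpha": config.alpha,
        "pooled_hybrids": config.pool_hybrids,
        "config_hash": config.config_hash(),
        "bones": bones,
        "n_specimens": len(dataset.specimens),
        "sex_stratified_bones": stratified_bones,
    }
    if truth is not None:
        bundle["truth"] = truth

    if config.output_dir is not None:
        write_bundle(bundle, config.output_dir)
    return bundle


def write_bundle(bundle: Mapping[str, Any], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(directory / f"{name}.csv", index=False, float_format="%.10g")
    with open(directory / "manifest.json", "w") as fh:
        json.dump(_jsonable(bundle["manifest"]), fh, indent=2, sort_keys=True)
    if "truth" in bundle and bundle["truth"] is not None:
        with open(directory / "truth.json", "w") as fh:
            json.dump(_jsonable(bundle["truth"].to_dict()), fh, indent=2, sort_keys=True)
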