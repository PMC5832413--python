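"""Pipeline driver: configuration, fixture emission, and the staged run.

``run_pipeline`` executes behavior models -> pattern loading -> first-level
RDMs -> second-level ROI statistics -> searchlight -> group inference and
overlap on a fixture directory (as emitted by :func:`write_fixture` / the
``sim`` CLI subcommand), writing all tables and maps plus a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, group, inference, io, rsa, searchlight, synth
from .glm import CONTEXTS, PatternSet
from .rdm import RDM

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fixture_dir: str
    out_dir: str
    seed: int
    min_count: int = 4
    exclude_tags: tuple[str, ...] = ("visual_form", "color")
    n_iter: int = 1000  # model randomization test iterations
    m_bonferroni: int = 16
    alpha: float = 0.05
    do_searchlight: bool = True
    k: int = 30
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    tfce_steps: int = 50
    connectivity: int = 26
    n_subject_null: int = 20
    n_group: int = 500

    def __post_init__(self) -> None:
        if self.min_count < 1 or self.n_iter < 1 or self.k < 1:
            raise ValueError("parameters out of range")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        data["exclude_tags"] = tuple(data.get("exclude_tags",
                                              ("visual_form", "color")))
        return cls(**data)


# ----------------------------------------------------------------------
# Fixture emission


def write_fixture(config: synth.SyntheticConfig, outdir: str | Path,
                  with_bold: bool = False) -> Path:
    """Emit a complete synthetic fixture directory.

    Contents: ratings/norms/embeddings TSV, events TSV, ground-truth model
    RDM CSVs and JSON, region + volume mask NIfTIs, and per-subject
    per-context run-averaged pattern stacks.  With ``with_bold``, raw BOLD
    series for subject 0 are included for GLM exercises.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    v, c = synth.make_model_rdms(config.n_objects, seed=config.seed)
    sim = synth.simulate_patterns(v, c, config)

    io.write_rdm_csv(v, outdir / "model_visual.csv")
    io.write_rdm_csv(c, outdir / "model_conceptual.csv")
    io.write_ratings_tsv(synth.simulate_ratings(v, config, seed=config.seed),
                         outdir / "ratings.tsv")
    io.write_norms_tsv(synth.simulate_norms(c, config, visual=v,
                                            seed=config.seed),
                       outdir / "norms.tsv")
    io.write_embeddings_tsv(
        synth.simulate_embeddings(c, v, leak=0.2, seed=config.seed,
                                  dim=max(64, config.n_objects)),
        outdir / "embeddings.tsv")

    events = _example_events(sim.object_labels, config.n_runs)
    io.write_events_tsv(events, outdir / "events.tsv")

    masks = outdir / "masks"
    masks.mkdir(exist_ok=True)
    io.save_mask(sim.volume_mask, config.affine, masks / "volume.nii")
    for name, m in sim.region_masks.items():
        io.save_mask(m, config.affine, masks / f"{name}.nii")

    patterns = outdir / "patterns"
    patterns.mkdir(exist_ok=True)
    for s in range(config.n_subjects):
        for ctx in CONTEXTS:
            ps = sim.averaged(s, ctx)
            io.save_patterns(ps, sim.volume_mask, config.affine,
                             patterns / f"sub{s:02d}_{ctx}.nii")

    if with_bold:
        bold = outdir / "bold"
        bold.mkdir(exist_ok=True)
        rng = np.random.default_rng(config.seed)
        amp = rng.normal(0, 1, size=(config.n_objects, 16))
        for run in sorted(events["run"].unique()):
            ev = events[events["run"] == run]
            bs = synth.simulate_bold(ev, amp, noise_sd=1.0,
                                     seed=config.seed + int(run))
            io.save_volume(bs.data[:, None, None, :].transpose(1, 2, 3, 0),
                           np.eye(4), bold / f"sub00_run{run}.nii")

    gt = {
        "tau_vc": sim.ground_truth.tau_vc,
        "regions": {name: {"weights": spec.weights,
                           "share_profiles": spec.shares}
                    for name, spec in config.regions.items()},
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "regions"},
    }
    (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    return outdir


def _example_events(objects: list[str], n_runs: int,
                    duration: float = 2.0) -> pd.DataFrame:
    rows = []
    for run in range(n_runs):
        t = 8.0
        for half, ctx in enumerate(CONTEXTS):
            order = np.roll(objects, run + half)
            for obj in order:
                rows.append((round(t, 2), duration, obj, run, ctx))
                t += 4.0
            t += 12.0
    return pd.DataFrame(rows, columns=["onset", "duration", "object",
                                       "run", "context"])


# ----------------------------------------------------------------------
# Staged run


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages on a fixture directory; returns the manifest."""
    fixture = Path(config.fixture_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [],
                      "parameters": dataclasses.asdict(config), "events": []}

    def stage(name):
        manifest["stages"].append(name)
        log.info("stage: %s", name)

    try:
        # ---- behavior models ------------------------------------------
        stage("behavior")
        ratings = io.read_ratings_tsv(fixture / "ratings.tsv")
        kept = behavior.filter_raters(ratings)
        n_excl = ratings["rater_id"].nunique() - kept["rater_id"].nunique()
        if n_excl:
            manifest["events"].append(f"behavior: excluded {n_excl} rater(s)")
        visual = behavior.visual_rdm(kept)
        norms = io.read_norms_tsv(fixture / "norms.tsv")
        cfm = behavior.filter_features(norms, min_count=config.min_count,
                                       exclude_tags=set(config.exclude_tags))
        conceptual = behavior.conceptual_rdm(cfm)
        embeddings = io.read_embeddings_tsv(fixture / "embeddings.tsv")
        emb_rdm = behavior.embedding_rdm(embeddings, visual.labels)
        for name, rdm in [("visual", visual), ("conceptual", conceptual),
                          ("embedding", emb_rdm)]:
            io.write_rdm_csv(rdm, out / f"behavior_{name}_rdm.csv")
        model_cmp = {}
        for pair in [("visual", "conceptual"), ("embedding", "conceptual"),
                     ("embedding", "visual")]:
            a = {"visual": visual, "conceptual": conceptual,
                 "embedding": emb_rdm}
            res = inference.randomization_test(a[pair[0]], a[pair[1]],
                                               n_iter=config.n_iter,
                                               seed=config.seed)
            model_cmp["_vs_".join(pair)] = {
                "tau_a": res.tau_a, "p": res.p, "n_null": res.n_null,
                "null_sd": res.null_sd}
        (out / "model_comparisons.json").write_text(
            json.dumps(model_cmp, indent=1))

        # ---- patterns -------------------------------------------------
        stage("patterns")
        pattern_files = sorted((fixture / "patterns").glob("sub*_*.nii"))
        if not pattern_files:
            raise FileNotFoundError("no pattern stacks in fixture/patterns")
        volume_mask, affine = io.load_mask(fixture / "masks" / "volume.nii")
        subjects = sorted({f.name.split("_")[0] for f in pattern_files})
        patterns: dict[tuple[str, str], PatternSet] = {}
        for f in pattern_files:
            sub, ctx = f.stem.split("_")
            ps, _ = io.load_patterns(f, volume_mask)
            patterns[(sub, ctx)] = ps
        region_masks = {
            p.stem: io.load_mask(p)[0]
            for p in sorted((fixture / "masks").glob("*.nii"))
            if p.stem != "volume"
        }
        flat = {name: m[volume_mask] for name, m in region_masks.items()}

        # ---- first level ----------------------------------------------
        stage("first_level")
        first = out / "first_level"
        first.mkdir(exist_ok=True)
        roi_rdms: dict[tuple[str, str, str], RDM] = {}
        for (sub, ctx), ps in patterns.items():
            for region, sel in flat.items():
                local = ps.subset(np.nonzero(sel)[0])
                local.roi = region
                rdm = rsa.pattern_rdm(local)
                roi_rdms[(sub, ctx, region)] = rdm
                io.write_rdm_csv(rdm, first / f"{sub}_{ctx}_{region}.csv")

        # ---- second level ---------------------------------------------
        stage("second_level")
        models = {"visual_model": visual.reorder(patterns[
            (subjects[0], "visual")].object_labels),
            "conceptual_model": conceptual.reorder(patterns[
                (subjects[0], "visual")].object_labels)}
        rows = []
        stat_cols: dict[str, np.ndarray] = {}
        for region in flat:
            for ctx in CONTEXTS:
                subject_rdms = [roi_rdms[(sub, ctx, region)]
                                for sub in subjects]
                for mname, model in models.items():
                    fit = inference.group_model_fit(
                        subject_rdms, model, m_comparisons=config.m_bonferroni,
                        alpha=config.alpha,
                        comparison=f"{region}:{ctx}:{mname}")
                    rows.append({"region": region, "context": ctx,
                                 "model": mname, "mean_tau": fit.mean_tau,
                                 "p": fit.p, "p_adjusted": fit.p_adjusted,
                                 "significant": fit.significant})
                    stat_cols[f"{region}|{ctx}|{mname}"] = fit.tau_per_subject
        roi_table = pd.DataFrame(rows)
        roi_table.to_csv(out / "roi_second_level.tsv", sep="\t", index=False)
        io.write_stat_table_tsv(
            pd.DataFrame(stat_cols, index=subjects), out / "subject_taus.tsv")

        within_rows = []
        for region, sel in flat.items():
            for sub in subjects:
                a = patterns[(sub, "visual")].subset(np.nonzero(sel)[0])
                b = patterns[(sub, "conceptual")].subset(np.nonzero(sel)[0])
                res = rsa.within_object_similarity(a, b)
                within_rows.append({"region": region, "subject": sub,
                                    "mean_r": res.mean})
        pd.DataFrame(within_rows).to_csv(out / "within_object.tsv",
                                         sep="\t", index=False)

        # 2x2 ANOVA per region: model x context on Fisher-z(sin) taus
        anova = {}
        for region in flat:
            table = np.column_stack([
                inference.fisher_z(inference.tau_to_r(np.clip(
                    stat_cols[f"{region}|{ctx}|{m}"], -0.999, 0.999)))
                for ctx, m in [("visual", "visual_model"),
                               ("visual", "conceptual_model"),
                               ("conceptual", "visual_model"),
                               ("conceptual", "conceptual_model")]])
            eff = inference.rm_anova_2x2(table)["interaction"]
            anova[region] = {"F": eff.F, "df": list(eff.df), "p": eff.p}
        (out / "roi_anova.json").write_text(json.dumps(anova, indent=1))

        if not config.do_searchlight:
            manifest["events"].append("searchlight/group skipped by config")
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            return manifest

        # ---- searchlight ----------------------------------------------
        stage("searchlight")
        nb = searchlight.build_neighborhoods(volume_mask, affine, k=config.k)
        sl_dir = out / "searchlight"
        sl_dir.mkdir(exist_ok=True)
        sl_maps: dict[tuple[str, str], list] = {}
        for ctx in CONTEXTS:
            for mname, model in models.items():
                maps = []
                for sub in subjects:
                    sm = searchlight.searchlight_fit(patterns[(sub, ctx)],
                                                     model, nb)
                    maps.append(sm)
                    io.save_volume(sm.volume(), affine,
                                   sl_dir / f"{sub}_{ctx}_{mname}.nii")
                sl_maps[(ctx, mname)] = maps

        # ---- group inference + overlap --------------------------------
        stage("group")
        group_dir = out / "group"
        group_dir.mkdir(exist_ok=True)
        thresholded = {}
        for (ctx, mname), maps in sl_maps.items():
            res = group.permutation_null(
                [patterns[(sub, ctx)] for sub in subjects],
                models[mname], nb,
                n_subject_null=config.n_subject_null, n_group=config.n_group,
                seed=config.seed, alpha=config.alpha, E=config.tfce_e,
                H=config.tfce_h, n_steps=config.tfce_steps,
                connectivity=config.connectivity)
            tag = f"{ctx}_{mname}"
            io.save_volume(res.group_z.volume(), affine,
                           group_dir / f"z_{tag}.nii")
            io.save_volume(res.threshold_mask.astype(float), affine,
                           group_dir / f"sig_{tag}.nii")
            ct = group.cluster_report(res.threshold_mask, affine,
                                      stat=res.group_z.volume(),
                                      connectivity=config.connectivity)
            ct.to_csv(group_dir / f"clusters_{tag}.tsv", sep="\t", index=False)
            thresholded[tag] = res.threshold_mask
        inter, table = group.overlap(list(thresholded.values()), affine,
                                     connectivity=config.connectivity)
        io.save_volume(inter.astype(float), affine, group_dir / "overlap.nii")
        table.to_csv(group_dir / "overlap_clusters.tsv", sep="\t", index=False)

        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception as exc:
        current = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {current!r}: {exc}") from exc
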