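"""End-to-end orchestration: simulate -> score -> contrast -> concord ->
compose -> test, with TSV/JSON reports.

The principal output mirrors the per-complex signal table of a mito-nuclear
discordance analysis: ΔCLS, average ΔCLS, strong-site percentages and the
focal-branch sCF for both candidate resolutions, joined per OXPHOS complex
group, plus the contact-marker comparison and the clade composition tests.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition as comp
from .alignment import Alignment
from .concordance import gcf, scf_for_split, scf_per_marker
from .contrast import complex_scores, delta_sls, sh_test
from .grouptests import ContactComparison, compare_contact_groups, dunn_bonferroni
from .likelihood import SiteScoreTable, optimize_branch_lengths, score_topologies
from .models import build_model
from .simulate import SimConfig, StudyFixture, make_study_fixture
from .trees import tree_from_string


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a full pipeline run depends on (seed included)."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str | Path | None = None
    label_mt: str = "mt"
    label_nuc: str = "nuc"
    threshold: float = 0.5
    n_quartets: int = 100
    n_sh_resamples: int = 1000
    optimize: bool = True
    optimize_tol: float = 0.1       # nats; ML-tool-style convergence
    optimize_xatol: float = 1e-4
    code_table: int = 5

    @property
    def seed(self) -> int:
        return self.sim.seed


@dataclass
class PipelineResult:
    config: RunConfig
    fixture: StudyFixture
    scores: SiteScoreTable
    dsls: np.ndarray
    marker_table: pd.DataFrame
    complex_table: pd.DataFrame        # the per-complex report incl. sCF
    sh_table: pd.DataFrame
    focal_scf: dict                    # label -> BranchConcordance
    marker_scf: dict
    focal_gcf: float | None
    contact: ContactComparison
    composition: pd.DataFrame
    ur_gt: pd.DataFrame
    clade_tests: dict                  # statistic -> PairwiseTestGrid
    timings: dict[str, float]
    total_delta_cls: float


def _stage(timings, name):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                raise StageError(name, exc) from exc
    return _Ctx()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the whole analysis on a (generated) study fixture."""
    timings: dict[str, float] = {}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    with _stage(timings, "simulate"):
        fx = make_study_fixture(config.sim,
                                out_dir / "fixture" if out_dir else None)
        model = build_model(config.sim.model_name, alpha=config.sim.alpha,
                            n_categories=config.sim.n_categories)
        tree_mt = tree_from_string(fx.pair.newick_a)
        tree_nuc = tree_from_string(fx.pair.newick_b)

    with _stage(timings, "optimize"):
        if config.optimize:
            tree_mt = optimize_branch_lengths(
                fx.alignment, tree_mt, model,
                tol=config.optimize_tol, xatol=config.optimize_xatol).tree
            tree_nuc = optimize_branch_lengths(
                fx.alignment, tree_nuc, model,
                tol=config.optimize_tol, xatol=config.optimize_xatol).tree

    with _stage(timings, "score"):
        scores = score_topologies(
            fx.alignment,
            {config.label_mt: tree_mt, config.label_nuc: tree_nuc}, model)

    with _stage(timings, "contrast"):
        dsls = delta_sls(scores, config.label_mt, config.label_nuc)
        site_part = fx.alignment.site_partition_index()
        marker_table = complex_scores(dsls, site_part,
                                      threshold=config.threshold)
        complex_table = complex_scores(dsls, site_part, fx.marker_complex,
                                       threshold=config.threshold)
        sh_table = sh_test(scores.scores, config.n_sh_resamples,
                           seed=config.seed)

    with _stage(timings, "concord"):
        split_mt = set(fx.pair.split_a)
        split_nuc = set(fx.pair.split_b)
        ref = tree_from_string(fx.pair.newick_a)
        focal = scf_for_split(fx.alignment, ref, split_mt,
                              config.n_quartets, config.seed)
        # which alternative resolution pairs the nuc-topology's groups?
        ga, _, gc_, _ = focal.groups
        all_taxa = set(fx.alignment.taxa)
        pairing_ac = set(ga) | set(gc_)
        nuc_attr = ("scf_alt1" if pairing_ac in (split_nuc, all_taxa - split_nuc)
                    else "scf_alt2")
        marker_scf = scf_per_marker(fx.alignment, ref, split_mt,
                                    config.n_quartets, config.seed)
        per_complex_scf = {}
        by_group: dict[str, list[str]] = {}
        for m, g in fx.marker_complex.items():
            by_group.setdefault(g, []).append(m)
        for g, markers in by_group.items():
            cols = np.concatenate([
                np.arange(*fx.alignment.partitions[m]) for m in markers])
            sub = Alignment(list(fx.alignment.taxa),
                            fx.alignment.matrix[:, cols],
                            fx.alignment.alphabet)
            bc = scf_for_split(sub, ref, split_mt, config.n_quartets,
                               config.seed)
            per_complex_scf[g] = bc
        gene_trees = [tree_from_string(nwk) for nwk in fx.gene_trees.values()]
        gcf_table = gcf(gene_trees, ref)
        focal_key = frozenset(focal.branch)
        focal_gcf = None
        for key, bc in gcf_table.items():
            if key == focal_key or key == frozenset(
                    set(fx.alignment.taxa) - set(focal.branch)):
                focal_gcf = bc.gcf
        complex_table = complex_table.assign(
            scf_mt=[_maybe(per_complex_scf.get(g),
                           "scf_main") for g in complex_table.group],
            scf_nuc=[_maybe(per_complex_scf.get(g),
                            nuc_attr) for g in complex_table.group],
        )

    with _stage(timings, "contact"):
        contact = compare_contact_groups(
            {m: (bc.scf_main if bc.defined else None)
             for m, bc in marker_scf.items()},
            fx.marker_contact)

    with _stage(timings, "compose"):
        composition = comp.composition_table(
            fx.cds, fx.taxon_clade, config.code_table)
        ur_rows = []
        for taxon, genome in fx.genomes.items():
            ur_rows.append({
                "taxon": taxon,
                "clade": fx.taxon_clade.get(taxon, "unassigned"),
                "ur_gt_content": comp.ur_gt_content(genome, fx.annotation),
            })
        ur_gt = pd.DataFrame(ur_rows)

    with _stage(timings, "test"):
        clade_tests = {}
        clades = sorted(set(fx.taxon_clade.values()))
        for stat in ["at_skew", "gt_content", "gt_rich_codon_freq",
                     "fourfold_gt3"]:
            groups = [composition.loc[composition.clade == c, stat]
                      .dropna().to_numpy() for c in clades]
            clade_tests[stat] = dunn_bonferroni(groups, clades)

    result = PipelineResult(
        config=config, fixture=fx, scores=scores, dsls=dsls,
        marker_table=marker_table, complex_table=complex_table,
        sh_table=sh_table,
        focal_scf={config.label_mt: focal},
        marker_scf=marker_scf, focal_gcf=focal_gcf, contact=contact,
        composition=composition, ur_gt=ur_gt, clade_tests=clade_tests,
        timings=timings,
        total_delta_cls=float(dsls.sum()),
    )
    if out_dir:
        with _stage(timings, "write"):
            _write_reports(result, out_dir)
    return result


def _maybe(bc, attr):
    if bc is None:
        return np.nan
    v = getattr(bc, attr)
    return np.nan if v is None else v


def _write_reports(res: PipelineResult, out_dir: Path) -> None:
    na = "NA"
    res.scores.to_tsv(out_dir / "site_scores.tsv")
    res.marker_table.to_csv(out_dir / "contrast_marker.tsv", sep="\t",
                            index=False, na_rep=na, float_format="%.10g")
    res.complex_table.to_csv(out_dir / "contrast_complex.tsv", sep="\t",
                             index=False, na_rep=na, float_format="%.10g")
    res.sh_table.to_csv(out_dir / "sh_test.tsv", sep="\t", index=False,
                        na_rep=na, float_format="%.10g")
    rows = []
    for m, bc in res.marker_scf.items():
        rows.append({"marker": m, "scf_mt": _maybe(bc, "scf_main"),
                     "scf_alt1": _maybe(bc, "scf_alt1"),
                     "scf_alt2": _maybe(bc, "scf_alt2"),
                     "n_quartets": bc.n_quartets})
    pd.DataFrame(rows).to_csv(out_dir / "scf_marker.tsv", sep="\t",
                              index=False, na_rep=na, float_format="%.10g")
    res.composition.to_csv(out_dir / "composition.tsv", sep="\t", index=False,
                           na_rep=na, float_format="%.10g")
    res.ur_gt.to_csv(out_dir / "ur_gt.tsv", sep="\t", index=False,
                     na_rep=na, float_format="%.10g")
    tests = {}
    for stat, grid in res.clade_tests.items():
        tests[stat] = {
            "kruskal_wallis_h": grid.h_statistic,
            "kruskal_wallis_p": grid.h_p_value,
            "pairs": grid.pairs.to_dict(orient="records"),
        }
    contact = {
        "t": res.contact.test.t, "df": res.contact.test.df,
        "p_value": res.contact.test.p_value,
        "summary": res.contact.summary.to_dict(),
        "n_missing": res.contact.n_missing,
        "plurality_threshold": res.contact.plurality_threshold,
    }
    manifest = {
        "seed": res.config.seed,
        "config_hash": res.fixture.manifest["config_hash"],
        "threshold": res.config.threshold,
        "n_quartets": res.config.n_quartets,
        "total_delta_cls": res.total_delta_cls,
        "focal_gcf": res.focal_gcf,
        "timings_s": res.timings,
    }
    (out_dir / "clade_tests.json").write_text(
        json.dumps(tests, indent=1, sort_keys=True) + "\n")
    (out_dir / "contact_test.json").write_text(
        json.dumps(contact, indent=1, sort_keys=True) + "\n")
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
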