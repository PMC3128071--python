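"""End-to-end orchestration: extraction -> filters -> ages -> statistics -> simulation.

`run_analysis` sequences the stages over a directory of per-species inputs
and emits deterministic TSV/JSON reports. `report_minimal_space` summarises a
length-summary table into per-orientation lower-limit ranges and per-species
minimal-promoter-length estimates.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .age import RegionIndex, annotate_ages, build_ortholog_map, scheme_from_tree
from .io_formats import read_annotation, read_homology_table, read_ortholog_table, read_repeat_bed, read_tree
from .neutral import (
    MODEL_A,
    MODEL_B,
    SimConfig,
    compare_distributions,
    right_tail_excess,
    simulate_survivors,
)
from .regions import (
    AGE_OLD,
    AGE_YOUNG,
    CONVERGENT,
    DIVERGENT,
    ORIENTATIONS,
    UNIDIRECTIONAL,
    build_neighbor_pairs,
    filter_repeats,
    filter_tandem,
    write_region_table,
)
from .stats import compare_fits, fit_gaussians, orientation_composition_test, summarize_lengths

logger = logging.getLogger(__name__)

PROMOTER_ORIENTATIONS = (DIVERGENT, UNIDIRECTIONAL)


def load_reference_summary() -> pd.DataFrame:
    """The shipped published per-species summary (means and lower limits, bp)."""
    ref = importlib.resources.files("intercds.data") / "reference_summary_11yeasts.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["species", "age", "orientation", "mean_bp", "lower_limit_bp"],
        )


def reference_tree_path() -> str:
    ref = importlib.resources.files("intercds.data") / "yeast11.nwk"
    with importlib.resources.as_file(ref) as path:
        return str(path)


@dataclass
class RunConfig:
    gene_files: Mapping[str, str]  # species -> tabular gene file
    tree_file: str
    ortholog_files: Sequence[str] = ()
    homology_file: str | None = None
    repeat_files: Mapping[str, str] = field(default_factory=dict)
    focal_species: Sequence[str] = ()  # default: all species
    n_age_classes: int | None = None  # None -> young/old only
    age_class_labels: Sequence[str] | None = None
    lower_limit_method: str = "quantile"
    lower_limit_q: float = 0.01
    fit_bin_width: float = 0.1
    sim_model: str = MODEL_A
    sim_replicates: int = 10
    sim_removal_mode: str = "sequential"
    seed: int = 0
    out_dir: str = "intercds_out"
    composition_window: tuple[float, float] = (1.0, 1e9)

    def validate(self) -> None:
        missing = [
            p
            for p in [self.tree_file, self.homology_file, *self.gene_files.values(),
                      *self.ortholog_files, *self.repeat_files.values()]
            if p is not None and not os.path.exists(p)
        ]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    @classmethod
    def from_json(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw.update(overrides)
        if "composition_window" in raw:
            raw["composition_window"] = tuple(raw["composition_window"])
        return cls(**raw)


def _float(x: float) -> float:
    return float(f"{x:.6g}")


def run_analysis(config: RunConfig) -> dict:
    """Run the full analysis; write reports into config.out_dir.

    Outputs: regions_<sp>.tsv (annotated region tables), table1_replica.tsv,
    fits.json, composition_test.tsv, sim_vs_observed.tsv, correlations.tsv
    and run_log.json. Deterministic for identical (inputs, config, seed).
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)

    tree = read_tree(config.tree_file)
    hits = read_homology_table(config.homology_file) if config.homology_file else []
    orthologs = []
    for path in config.ortholog_files:
        orthologs.extend(read_ortholog_table(path))

    regions_by_sp = {}
    for sp, path in sorted(config.gene_files.items()):
        genes = read_annotation(path, format="tabular")
        regs = build_neighbor_pairs(genes)
        regs = filter_tandem(regs, hits)
        if sp in config.repeat_files:
            regs = filter_repeats(regs, read_repeat_bed(config.repeat_files[sp], sp))
        regions_by_sp[sp] = regs

    species = sorted(regions_by_sp)
    focal_list = list(config.focal_species) or species
    indexes = {sp: RegionIndex(regions_by_sp[sp]) for sp in species}

    annotated = {}
    for focal in focal_list:
        scheme = None
        if config.n_age_classes is not None:
            scheme = scheme_from_tree(
                tree, focal, config.n_age_classes, labels=config.age_class_labels
            )
        omaps = {
            sp: build_ortholog_map(orthologs, focal, sp)
            for sp in species
            if sp != focal
        }
        labelled, _ = annotate_ages(
            regions_by_sp[focal], focal,
            {sp: indexes[sp] for sp in species if sp != focal}, omaps, scheme,
        )
        annotated[focal] = labelled
        write_region_table(labelled, os.path.join(config.out_dir, f"regions_{focal}.tsv"))

    all_regions = [r for focal in focal_list for r in annotated[focal]]
    replica = summarize_lengths(
        all_regions, config.lower_limit_method, config.lower_limit_q
    )
    replica.to_csv(os.path.join(config.out_dir, "table1_replica.tsv"), sep="\t", index=False)

    # per-stratum 1- vs 2-Gaussian fits on old lengths
    fits_report: dict = {}
    for focal in focal_list:
        for orientation in ORIENTATIONS:
            lengths = [
                r.length for r in annotated[focal]
                if r.retained and r.age_label == AGE_OLD and r.orientation == orientation
            ]
            key = f"{focal}:{orientation}"
            if len(lengths) < 50:
                fits_report[key] = {"n": len(lengths), "skipped": "n < 50"}
                continue
            f1 = fit_gaussians(lengths, 1, config.fit_bin_width, seed=config.seed)
            f2 = fit_gaussians(lengths, 2, config.fit_bin_width, seed=config.seed)
            cmp_ = compare_fits(f1, f2)
            fits_report[key] = {
                "n": len(lengths),
                "k1": _fit_json(f1),
                "k2": _fit_json(f2),
                "f_statistic": _float(cmp_.f_statistic),
                "p_value": _float(cmp_.p_value),
            }
    with open(os.path.join(config.out_dir, "fits.json"), "w") as fh:
        json.dump(fits_report, fh, indent=1, sort_keys=True)

    comp_rows = []
    for focal in focal_list:
        test = orientation_composition_test(annotated[focal], config.composition_window)
        comp_rows.append(
            {"species": focal, "chi2": _float(test.chi2), "p_value": _float(test.p_value),
             "n_divergent": test.observed[0], "n_unidirectional": test.observed[1],
             "n_convergent": test.observed[2]}
        )
    pd.DataFrame(comp_rows).to_csv(
        os.path.join(config.out_dir, "composition_test.tsv"), sep="\t", index=False
    )

    # neutral simulation per focal species x orientation
    sim_rows = []
    rng = np.random.default_rng(config.seed)
    for focal in focal_list:
        for orientation in ORIENTATIONS:
            stratum = [
                r for r in annotated[focal]
                if r.retained and r.orientation == orientation
                and r.age_label in (AGE_OLD, AGE_YOUNG)
            ]
            old = [r.length for r in stratum if r.age_label == AGE_OLD]
            young = [r.length for r in stratum if r.age_label == AGE_YOUNG]
            if not old or not young:
                continue
            offset = 0.0
            if config.sim_model == MODEL_B and orientation in PROMOTER_ORIENTATIONS:
                row = replica[
                    (replica.species == focal) & (replica.age == AGE_OLD)
                    & (replica.orientation == orientation)
                ]
                offset = float(row.lower_limit_bp.iloc[0])
            sim_cfg = SimConfig(
                model=config.sim_model, n_young=len(young), promoter_offset=offset,
                replicates=config.sim_replicates,
                seed=int(rng.integers(2**31 - 1)),
                removal_mode=config.sim_removal_mode,
                bin_width_log10=config.fit_bin_width,
            )
            sim = simulate_survivors([r.length for r in stratum], sim_cfg)
            rep = compare_distributions(sim, old)
            tail = right_tail_excess(rep, old)
            sim_rows.append(
                {"species": focal, "orientation": orientation, "model": config.sim_model,
                 "n_total": len(stratum), "n_young": len(young),
                 "promoter_offset": _float(offset),
                 "ks_statistic": _float(rep.ks_statistic),
                 "ks_p_value": _float(rep.ks_p_value),
                 "right_tail_excess": _float(float(tail))}
            )
    pd.DataFrame(sim_rows).to_csv(
        os.path.join(config.out_dir, "sim_vs_observed.tsv"), sep="\t", index=False
    )

    # cross-species correlations of the minimal-space proxy
    corr_rows = []
    if len(focal_list) >= 3:
        from .stats import correlate

        proxy, intergenic, genic = [], [], []
        for focal in focal_list:
            row = replica[
                (replica.species == focal) & (replica.age == AGE_OLD)
                & (replica.orientation == DIVERGENT)
            ]
            if row.empty or pd.isna(row.lower_limit_bp.iloc[0]):
                continue
            proxy.append(float(row.lower_limit_bp.iloc[0]))
            retained = [r for r in annotated[focal] if r.retained]
            intergenic.append(float(sum(r.length for r in retained)))
            genes = read_annotation(config.gene_files[focal], format="tabular")
            genic.append(float(sum(g.cds_end - g.cds_start + 1 for g in genes)))
        if len(proxy) >= 3:
            for name, y in [("total_intergenic_space", intergenic),
                            ("genome_size", [a + b for a, b in zip(intergenic, genic)]),
                            ("total_coding_length", genic)]:
                try:
                    r, p = correlate(proxy, y)
                except ValueError:
                    continue
                corr_rows.append(
                    {"x": "old_divergent_lower_limit", "y": name,
                     "n": len(proxy), "pearson_r": _float(r), "p_value": _float(p)}
                )
    pd.DataFrame(
        corr_rows, columns=["x", "y", "n", "pearson_r", "p_value"]
    ).to_csv(os.path.join(config.out_dir, "correlations.tsv"), sep="\t", index=False)

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "species": species,
        "focal_species": focal_list,
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else list(v) if isinstance(v, (list, tuple)) else v)
            for k, v in vars(config).items()
        },
        "n_regions": {sp: len(regions_by_sp[sp]) for sp in species},
    }
    with open(os.path.join(config.out_dir, "run_log.json"), "w") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True, default=str)
    return {
        "replica": replica,
        "fits": fits_report,
        "composition": comp_rows,
        "simulation": sim_rows,
        "correlations": corr_rows,
        "regions": annotated,
    }


def _fit_json(fit) -> dict:
    return {
        "components": [
            {"mean": _float(c.mean), "sd": _float(c.sd), "weight": _float(c.weight)}
            for c in fit.components
        ],
        "rss": _float(fit.rss),
        "n_params": fit.n_params,
    }


def report_minimal_space(replica: pd.DataFrame) -> dict:
    """Summarise lower limits and minimal-promoter-length estimates.

    Per orientation: min/max of the OLD lower limits across species. The
    minimal promoter length per species and promoter-containing orientation
    is that stratum's old lower limit minus the old CONVERGENT lower limit
    (the promoter-less baseline). The convergent lower limit — not the
    convergent mean — is used: subtracting the mean produces negative
    estimates for most compact species, which is logged as a caveat.
    """
    logger.info(
        "minimal-promoter estimates subtract the convergent LOWER LIMIT "
        "(subtracting the convergent mean yields negative values for several species)"
    )
    old = replica[replica.age == AGE_OLD].set_index(["species", "orientation"])
    out: dict = {"lower_limit_range": {}, "promoter_length_estimates": []}
    for orientation in ORIENTATIONS:
        vals = [
            old.loc[(sp, orientation), "lower_limit_bp"]
            for sp, o in old.index
            if o == orientation
        ]
        vals = [float(v) for v in vals if not pd.isna(v)]
        if vals:
            out["lower_limit_range"][orientation] = {
                "min": min(vals), "max": max(vals),
            }
    species = sorted({sp for sp, _ in old.index})
    for sp in species:
        try:
            conv = float(old.loc[(sp, CONVERGENT), "lower_limit_bp"])
        except KeyError:
            continue
        if pd.isna(conv):
            continue
        for orientation in PROMOTER_ORIENTATIONS:
            try:
                ll = float(old.loc[(sp, orientation), "lower_limit_bp"])
            except KeyError:
                continue
            if pd.isna(ll):
                continue
            out["promoter_length_estimates"].append(
                {"species": sp, "orientation": orientation, "estimate_bp": ll - conv}
            )
    ests = [e["estimate_bp"] for e in out["promoter_length_estimates"]]
    if ests:
        out["promoter_length_range"] = {"min": min(ests), "max": max(ests)}
    return out
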