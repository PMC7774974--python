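"""Configuration-driven orchestration of the analysis stages.

A single YAML config declares inputs, seeds, permutation counts and the
stages to run; every table is written with a comment header recording
inputs, seeds, parameters and the package version.  Runs are deterministic
for a fixed config and seed.  On any stage failure the partial outputs of
that run are removed and the error propagated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .amova import amova, pairwise_distance_matrix
from .admixture import bin_by_component
from .demography import classic_skyline, median_skyline_trajectory
from .diversity import diversity_report
from .haplogroups import HaplogroupCalls, frequency_table, haplogroup_resampling_test
from .io import (
    _write_tsv,
    read_fasta_alignment,
    read_genotype_table,
    read_population_map,
    read_qmatrix,
    read_str_table,
    write_fasta_alignment,
    write_genotype_table,
    write_population_map,
    write_qmatrix,
    write_str_table,
    apply_site_mask,
)
from .ordination import classical_mds, pcoa_individuals
from .simulate import female_history, male_history, simulate_genealogy, study_scenario

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("perupop")

STAGES = (
    "simulate", "diversity", "distances", "amova", "mds", "pcoa",
    "haplogroup-test", "admixture-bin", "skyline",
)


@dataclass
class PipelineConfig:
    stages: list[str]
    out_dir: str
    seed: int = 0
    permutations: int = 10_000
    level: str = "region"
    inputs: dict = field(default_factory=dict)  # fasta, popmap, str_table, genotypes, qmatrix, calls, ref_freqs
    grouping: dict | None = None
    mask_exclude: list | None = None  # [[lo, hi], ...]
    mask_restrict: list | None = None  # [lo, hi]
    bin_component: int = 2
    skyline_model: str = "male"
    skyline_samples: int = 60
    skyline_replicates: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        for key, p in self.inputs.items():
            if key != "ref_freqs" and not Path(p).exists():
                raise FileNotFoundError(f"input {key!r}: no such file {p}")


def _header(cfg: PipelineConfig, stage: str, **params) -> list[str]:
    lines = [f"perupop {__version__} stage={stage} seed={cfg.seed}"]
    for k, v in params.items():
        lines.append(f"{k}={v}")
    for k, v in sorted(cfg.inputs.items()):
        lines.append(f"input.{k}={v}")
    return lines


def _load_sequences(cfg: PipelineConfig):
    aln = read_fasta_alignment(cfg.inputs["fasta"])
    if cfg.mask_restrict or cfg.mask_exclude:
        aln = apply_site_mask(
            aln,
            exclude=[tuple(r) for r in (cfg.mask_exclude or [])],
            restrict=tuple(cfg.mask_restrict) if cfg.mask_restrict else None,
        )
    return aln


def _marker_data(cfg: PipelineConfig):
    """The marker table the distance stages operate on, by available input."""
    if "fasta" in cfg.inputs:
        return _load_sequences(cfg)
    if "str_table" in cfg.inputs:
        return read_str_table(cfg.inputs["str_table"])
    if "genotypes" in cfg.inputs:
        return read_genotype_table(cfg.inputs["genotypes"])
    raise FileNotFoundError("no marker input (fasta / str_table / genotypes) configured")


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Execute the configured stages in dependency order.

    Returns stage name -> primary output path.  Raises on the first stage
    error after removing that run's partial outputs.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict[str, Path] = {}

    def emit(name: str, header, columns, rows) -> Path:
        path = out / name
        _write_tsv(path, columns, rows, comments=header)
        written.append(path)
        return path

    try:
        for stage in [s for s in STAGES if s in cfg.stages]:
            log.info("stage %s", stage)
            if stage == "simulate":
                bundle = study_scenario(seed=cfg.seed)
                write_fasta_alignment(bundle.mt_alignment, out / "mt_alignment.fasta")
                write_population_map(bundle.mt_popmap, out / "mt_popmap.tsv")
                write_str_table(bundle.ystr_table, out / "ystr_table.tsv")
                write_population_map(bundle.ystr_popmap, out / "ystr_popmap.tsv")
                write_genotype_table(bundle.genotypes, out / "genotypes.tsv")
                write_qmatrix(bundle.qmatrix, out / "qmatrix.tsv")
                write_population_map(bundle.genotype_popmap, out / "genotype_popmap.tsv")
                for n in ("mt_alignment.fasta", "mt_popmap.tsv", "ystr_table.tsv",
                          "ystr_popmap.tsv", "genotypes.tsv", "qmatrix.tsv",
                          "genotype_popmap.tsv"):
                    written.append(out / n)
                results[stage] = out / "mt_alignment.fasta"
                # generated inputs feed later stages unless overridden
                cfg.inputs.setdefault("fasta", str(out / "mt_alignment.fasta"))
                cfg.inputs.setdefault("popmap", str(out / "mt_popmap.tsv"))
                cfg.inputs.setdefault("genotypes", str(out / "genotypes.tsv"))
                cfg.inputs.setdefault("qmatrix", str(out / "qmatrix.tsv"))

            elif stage == "diversity":
                data = _marker_data(cfg)
                popmap = read_population_map(cfg.inputs["popmap"])
                rows = [
                    [r.population, r.n,
                     "" if r.h is None else f"{r.h:.4f}",
                     "" if r.pi is None else f"{r.pi:.6g}",
                     "" if r.mnpd is None else f"{r.mnpd:.4f}"]
                    for r in diversity_report(data, popmap, level=cfg.level)
                ]
                results[stage] = emit(
                    "diversity.tsv", _header(cfg, stage, level=cfg.level),
                    ["population", "n", "h", "pi", "mnpd"], rows,
                )

            elif stage == "distances":
                data = _marker_data(cfg)
                popmap = read_population_map(cfg.inputs["popmap"])
                dm = pairwise_distance_matrix(
                    data, popmap, level=cfg.level,
                    permutations=cfg.permutations, seed=cfg.seed,
                )
                header = _header(cfg, stage, level=cfg.level,
                                 permutations=cfg.permutations, kind=dm.kind)
                rows = [
                    [lab, *(f"{x:.6f}" for x in dm.statistic[i])]
                    for i, lab in enumerate(dm.labels)
                ]
                results[stage] = emit(
                    "distances.tsv", header, ["population", *dm.labels], rows)
                prow = [
                    [lab, *(f"{x:.6g}" for x in dm.p_values[i])]
                    for i, lab in enumerate(dm.labels)
                ]
                emit("distances_p.tsv", header, ["population", *dm.labels], prow)

            elif stage == "amova":
                data = _marker_data(cfg)
                popmap = read_population_map(cfg.inputs["popmap"])
                grouping = (
                    {g: tuple(v) for g, v in cfg.grouping.items()} if cfg.grouping else None
                )
                res = amova(
                    data, popmap, grouping=grouping, level=cfg.level,
                    permutations=cfg.permutations, seed=cfg.seed,
                )
                rows = [
                    ["among_groups", res.df[0], f"{res.ssd[0]:.6f}",
                     f"{res.components[0]:.6f}", f"{res.percentages[0]:.2f}",
                     f"F_CT={res.f_ct:.6f}", f"{res.p_ct:.6g}"],
                    ["among_pops_within_groups", res.df[1], f"{res.ssd[1]:.6f}",
                     f"{res.components[1]:.6f}", f"{res.percentages[1]:.2f}",
                     f"F_SC={res.f_sc:.6f}", f"{res.p_sc:.6g}"],
                    ["within_pops", res.df[2], f"{res.ssd[2]:.6f}",
                     f"{res.components[2]:.6f}", f"{res.percentages[2]:.2f}",
                     f"F_ST={res.f_st:.6f}", f"{res.p_st:.6g}"],
                ]
                results[stage] = emit(
                    "amova.tsv",
                    _header(cfg, stage, level=cfg.level, grouping=res.grouping,
                            permutations=cfg.permutations,
                            degenerate=res.degenerate),
                    ["component", "df", "ssd", "variance", "percent", "index", "p"],
                    rows,
                )

            elif stage == "mds":
                data = _marker_data(cfg)
                popmap = read_population_map(cfg.inputs["popmap"])
                dm = pairwise_distance_matrix(
                    data, popmap, level=cfg.level, permutations=0, seed=cfg.seed)
                stat = np.maximum(dm.statistic, 0.0)  # negative estimates clip for embedding
                ord_res = classical_mds(stat, labels=dm.labels, k=2)
                rows = [
                    [lab, *(f"{c:.6f}" for c in ord_res.coordinates[i])]
                    for i, lab in enumerate(ord_res.labels)
                ]
                axes = [f"axis{j + 1}" for j in range(ord_res.coordinates.shape[1])]
                results[stage] = emit(
                    "mds.tsv",
                    _header(cfg, stage, level=cfg.level,
                            eigenvalues=ord_res.eigenvalues.tolist(),
                            proportion=ord_res.proportion_explained.tolist()),
                    ["population", *axes], rows,
                )

            elif stage == "pcoa":
                table = read_genotype_table(cfg.inputs["genotypes"])
                ord_res = pcoa_individuals(table, k=2)
                rows = [
                    [lab, *(f"{c:.6f}" for c in ord_res.coordinates[i])]
                    for i, lab in enumerate(ord_res.labels)
                ]
                axes = [f"axis{j + 1}" for j in range(ord_res.coordinates.shape[1])]
                results[stage] = emit(
                    "pcoa.tsv",
                    _header(cfg, stage,
                            proportion=ord_res.proportion_explained.tolist()),
                    ["sample_id", *axes], rows,
                )

            elif stage == "haplogroup-test":
                popmap = read_population_map(cfg.inputs["popmap"])
                calls = _read_calls(cfg.inputs["calls"])
                ref = cfg.inputs["ref_freqs"]
                if isinstance(ref, str):
                    with open(ref, encoding="utf-8") as fh:
                        ref = yaml.safe_load(fh)
                freq = frequency_table(calls, popmap, level=cfg.level)
                all_rows = []
                for pop in freq.populations:
                    counts = {h: c for h, c in freq.row(pop).items() if c or h in ref}
                    res = haplogroup_resampling_test(
                        counts, int(freq.counts[freq.populations.index(pop)].sum()),
                        ref, seed=cfg.seed,
                    )
                    for row in res.to_rows():
                        all_rows.append([pop, *row])
                results[stage] = emit(
                    "haplogroup_test.tsv",
                    _header(cfg, stage, level=cfg.level, draws=100_000),
                    ["population", "haplogroup", "observed", "null_mean",
                     "lo", "hi", "p", "flag"],
                    all_rows,
                )

            elif stage == "admixture-bin":
                q = read_qmatrix(cfg.inputs["qmatrix"])
                binning = bin_by_component(q, cfg.bin_component)
                rows = [[sid, f"{q.proportions[i, cfg.bin_component]:.4f}",
                         binning.bins[sid]]
                        for i, sid in enumerate(q.sample_ids)]
                results[stage] = emit(
                    "admixture_bins.tsv",
                    _header(cfg, stage, component=cfg.bin_component,
                            edges=binning.edges, counts=binning.counts()),
                    ["sample_id", "proportion", "bin"], rows,
                )

            elif stage == "skyline":
                model = (male_history() if cfg.skyline_model == "male"
                         else female_history())
                rng = np.random.default_rng(cfg.seed)
                skylines = [
                    classic_skyline(
                        simulate_genealogy(model, cfg.skyline_samples, rng))
                    for _ in range(cfg.skyline_replicates)
                ]
                grid = np.linspace(1.0, 600.0, 120)
                med = median_skyline_trajectory(skylines, grid)
                rows = [[f"{t:.1f}", f"{m:.2f}"] for t, m in zip(grid, med)]
                results[stage] = emit(
                    "skyline.tsv",
                    _header(cfg, stage, model=cfg.skyline_model,
                            samples=cfg.skyline_samples,
                            replicates=cfg.skyline_replicates),
                    ["generations_bp", "median_n_hat"], rows,
                )
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return results


def _read_calls(path) -> HaplogroupCalls:
    """TSV with columns sample_id, haplogroup."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").split("\t") for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    return HaplogroupCalls({r[0]: r[1] for r in lines[1:]})
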