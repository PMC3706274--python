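"""End-to-end orchestration: consensus calls -> TF profiles -> conserved TFs,
reference distances, and GO summaries, with plain-TSV reports and a
machine-readable run manifest.

The pipeline is a pure function of its inputs and configuration: given the
same files and the same config it writes byte-identical reports.  Each
comparison is either an expression matrix (the built-in pairwise caller is
used on every replicate pair) or a directory of precomputed per-pair
``.diff`` files from an external caller.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .consensus import (
    CallerConfig,
    ConsensusCall,
    calls_to_frame,
    consensus as consensus_tally,
    run_consensus_de,
    selected_genes,
)
from . import go as gomod
from . import io as xio
from . import profiles as prof
from .errors import ConfigError, InputError, XyloseqError

log = logging.getLogger("xyloseq")


class PipelineError(XyloseqError):
    """A pipeline stage failed; the message names the stage and comparison."""


@dataclass
class ComparisonSpec:
    """One control-vs-experiment comparison.

    Exactly one of ``expression`` (FPKM matrix + ``samples`` sidecar mapping
    sample -> condition) or ``diff_dir`` (directory of per-replicate-pair
    ``.diff`` files) must be given.
    """

    label: str
    control: str = "control"
    experiment: str = "experiment"
    expression: str | None = None
    samples: str | None = None
    diff_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.expression is None) == (self.diff_dir is None):
            raise ConfigError(
                f"comparison {self.label!r}: give exactly one of expression/diff_dir"
            )
        if self.expression is not None and self.samples is None:
            raise ConfigError(f"comparison {self.label!r}: expression needs a samples file")


@dataclass
class PipelineConfig:
    comparisons: list[ComparisonSpec]
    regulation: str
    go_mapping: str | None = None
    references: dict[str, str] = field(default_factory=dict)  # name -> ranking file
    cutoff_n: int = 9
    K: int = prof.DEFAULT_K
    n_ref_genes: int = prof.DEFAULT_N_REF_GENES
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    epsilon: float = 1.0
    require_consistent_direction: bool = True
    outdir: str = "xyloseq_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        comps = [ComparisonSpec(**c) for c in raw.pop("comparisons", [])]
        return cls(comparisons=comps, **raw)


def _read_samples_file(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"sample", "condition"} <= set(df.columns):
        raise ConfigError("samples file needs 'sample' and 'condition' columns")
    return dict(zip(df["sample"], df["condition"]))


def _read_ranking(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def _consensus_for(spec: ComparisonSpec, config: PipelineConfig) -> list[ConsensusCall]:
    if spec.expression is not None:
        matrix = xio.read_expression_table(spec.expression, _read_samples_file(spec.samples))
        return run_consensus_de(
            matrix,
            spec.control,
            spec.experiment,
            cutoff_n=config.cutoff_n,
            caller_config=CallerConfig(
                alpha=config.alpha,
                min_abs_log2fc=config.min_abs_log2fc,
                epsilon=config.epsilon,
            ),
            require_consistent_direction=config.require_consistent_direction,
        )
    diff_files = sorted(Path(spec.diff_dir).glob("*.diff"))
    if not diff_files:
        raise InputError(f"no .diff files in {spec.diff_dir}")
    tables = [xio.read_cuffdiff_diff(f, alpha=config.alpha) for f in diff_files]
    return consensus_tally(
        tables,
        config.cutoff_n,
        require_consistent_direction=config.require_consistent_direction,
    )


def _profile_tsv(profile: prof.TFProfile, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# label={profile.label}\tn_de_total={profile.n_de_total}\tK={profile.K}\n")
        fh.write("tf\tn_targets_in_de\tfraction\n")
        for e in profile.entries:
            fh.write(f"{e.tf_name}\t{e.n_targets_in_de}\t{e.fraction:.10g}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured comparison through consensus calling, TF
    profiling, and GO summarization; intersect the profiles for conserved
    TFs; and measure every sample profile's distance to every reference
    profile.  Reports are written under ``config.outdir``; the returned dict
    holds the in-memory results keyed the same way."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regulation = xio.read_regulation_table(config.regulation)
    go_mapping = xio.read_go_mapping(config.go_mapping) if config.go_mapping else None

    results: dict = {"calls": {}, "profiles": {}, "selected": {}}
    summaries = []
    for spec in config.comparisons:
        log.info("consensus stage: %s", spec.label)
        try:
            calls = _consensus_for(spec, config)
        except Exception as exc:
            raise PipelineError(
                f"consensus stage failed for comparison {spec.label!r}: {exc}"
            ) from exc
        results["calls"][spec.label] = calls
        calls_to_frame(calls).to_csv(
            outdir / f"consensus_{spec.label}.tsv", sep="\t", index=False
        )
        selected = selected_genes(calls)
        results["selected"][spec.label] = selected
        if selected:
            profile = prof.build_profile(selected, regulation, K=config.K, label=spec.label)
            results["profiles"][spec.label] = profile
            _profile_tsv(profile, outdir / f"profile_{spec.label}.tsv")
        if go_mapping is not None:
            summaries.append(gomod.summarize_go(calls, go_mapping, label=spec.label))

    if go_mapping is not None:
        merged = gomod.merge_summaries(summaries)
        results["go_summary"] = merged
        frame = merged.to_frame()
        with open(outdir / "go_summary.tsv", "w", encoding="utf-8") as fh:
            frame.to_csv(fh, sep="\t", index=False)
            fh.write("# totals (unique genes per direction)\n")
            for comp, by_dir in merged.totals.items():
                fh.write(f"# {comp}\tup={by_dir['up']}\tdown={by_dir['down']}\n")

    sample_profiles = list(results["profiles"].values())
    if sample_profiles:
        conserved = prof.conserved_tfs(sample_profiles)
        results["conserved_tfs"] = conserved
        (outdir / "conserved_tfs.tsv").write_text(
            "tf\n" + "".join(f"{tf}\n" for tf in conserved), encoding="utf-8"
        )

    if config.references and sample_profiles:
        ref_profiles = {
            name: prof.build_reference_profile(
                _read_ranking(path),
                regulation,
                n_ref_genes=config.n_ref_genes,
                K=config.K,
                label=name,
            )
            for name, path in sorted(config.references.items())
        }
        results["reference_profiles"] = ref_profiles
        rows = []
        for label, sp in results["profiles"].items():
            for name, rp in ref_profiles.items():
                rows.append((label, name, prof.profile_distance(sp, rp)))
        dist = pd.DataFrame(rows, columns=["comparison", "reference", "distance"])
        results["distances"] = dist
        dist.to_csv(outdir / "distances.tsv", sep="\t", index=False, float_format="%.10g")

    manifest = {
        "parameters": {
            "cutoff_n": config.cutoff_n,
            "K": config.K,
            "n_ref_genes": config.n_ref_genes,
            "alpha": config.alpha,
            "min_abs_log2fc": config.min_abs_log2fc,
            "epsilon": config.epsilon,
            "require_consistent_direction": config.require_consistent_direction,
        },
        "comparisons": [s.label for s in config.comparisons],
        "references": sorted(config.references),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    results["manifest"] = manifest
    return results


def write_synthetic_bundle(
    outdir: str | Path,
    seed: int = 0,
    n_pairs: int = 4,
    sim_config: "object | None" = None,
    n_tfs: int = 50,
    target_size_range: tuple[int, int] = (10, 50),
    n_conserved: int = 3,
    enrichment: float = 0.5,
) -> PipelineConfig:
    """Simulate a complete input bundle on disk and return a ready-to-run
    :class:`PipelineConfig` for it.

    Writes, per condition pair, an expression TSV and sample sidecar; plus a
    shared regulation table, GO mapping, two reference rankings, and the
    ground truth (planted DE genes and conserved TFs) as TSV.
    """
    from . import simulate as sim

    base = sim_config if sim_config is not None else sim.SimConfig(seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    comparisons = []
    truths = []
    for i in range(n_pairs):
        cfg = sim.SimConfig(
            **{
                **{f: getattr(base, f) for f in base.__dataclass_fields__},
                "seed": (seed * 1000 + i) % (2**31),
            }
        )
        matrix, truth = sim.simulate_expression(cfg)
        truths.append(truth)
        label = f"pair{i + 1}"
        xio.write_expression_table(matrix, outdir / f"expression_{label}.tsv")
        with open(outdir / f"samples_{label}.tsv", "w", encoding="utf-8") as fh:
            fh.write("sample\tcondition\n")
            for s in matrix.sample_ids:
                fh.write(f"{s}\t{matrix.condition_of[s]}\n")
        comparisons.append(
            ComparisonSpec(
                label=label,
                control=cfg.control_label,
                experiment=cfg.experiment_label,
                expression=str(outdir / f"expression_{label}.tsv"),
                samples=str(outdir / f"samples_{label}.tsv"),
            )
        )

    regulation, merged = sim.simulate_regulation(
        n_tfs=n_tfs,
        target_size_range=target_size_range,
        truth=truths,
        n_conserved=n_conserved,
        enrichment=enrichment,
        seed=(seed * 1000 + 777) % (2**31),
        n_genes_total=base.n_genes,
    )
    xio.write_regulation_table(regulation, outdir / "regulation.tsv")

    genes = sim._gene_ids(base.n_genes)
    go_mapping = sim.simulate_go_mapping(genes, seed=(seed * 1000 + 888) % (2**31))
    xio.write_go_mapping(go_mapping, outdir / "go_mapping.tsv")

    references = {}
    for j, name in enumerate(("xylose_reference", "stress_reference")):
        ranking = sim.simulate_reference_ranking(
            truths[j % len(truths)],
            n_genes_total=base.n_genes,
            seed=(seed * 1000 + 500 + j) % (2**31),
        )
        path = outdir / f"{name}_ranking.txt"
        path.write_text("".join(f"{g}\n" for g in ranking), encoding="utf-8")
        references[name] = str(path)

    with open(outdir / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("pair\tkind\tname\tdirection\n")
        for i, t in enumerate(truths):
            for g in sorted(t.de_genes):
                fh.write(f"pair{i + 1}\tde_gene\t{g}\t{t.de_genes[g]}\n")
        for tf in sorted(merged.conserved_tfs):
            fh.write(f"all\tconserved_tf\t{tf}\t-\n")

    return PipelineConfig(
        comparisons=comparisons,
        regulation=str(outdir / "regulation.tsv"),
        go_mapping=str(outdir / "go_mapping.tsv"),
        references=references,
        outdir=str(outdir / "reports"),
    )
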