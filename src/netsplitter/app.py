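"""Pipeline driver, configuration and command-line interface.

The pipeline proper is deterministic end to end — random walks are computed
analytically as probability matrices, clustering and cover selection break
ties deterministically — so a seed only enters synthetic fixture
generation.  The CLI is a thin layer over the library: ``split`` runs the
full pipeline, ``dag`` exports walk matrices, ``efficacy`` scores a size
list, ``validate`` runs the null-space check and ``synth`` generates
planted-module fixtures.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import numpy as np

from . import metrics, postprocess, synthetic
from .network_model import (
    ExternalsPolicy,
    StoichiometricNetwork,
    apply_externals_policy,
    detect_structural_externals,
    read_externals_list,
    read_sbml,
    read_tsv,
    write_subnet,
    write_tsv,
)
from .separators import AutoController, InteractiveController, SeparatorConfig, run_rounds
from .walk_dag import build_adjacency, build_transition, converge_dag

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_network", "main"]


@dataclass
class RunConfig:
    """Everything a batch run needs; serialisable to/from plain JSON."""

    connectivity_threshold: int | None = 8
    force_external: list[str] = field(default_factory=list)
    force_internal: list[str] = field(default_factory=list)
    structural_pass: bool = True
    separators: SeparatorConfig = field(default_factory=SeparatorConfig)
    merge_overlaps: bool = False
    interactive: bool = False

    def policy(self) -> ExternalsPolicy:
        return ExternalsPolicy(
            connectivity_threshold=self.connectivity_threshold,
            force_external=set(self.force_external),
            force_internal=set(self.force_internal),
        )


@dataclass
class PipelineResult:
    partition: postprocess.Partition
    structural_externals: set[str]
    policy_externals: set[str]
    n_internal_initial: int
    efficacy: metrics.EfficacyReport | None = None
    nullspace: metrics.NullspaceReport | None = None


def load_network(path: str | Path) -> StoichiometricNetwork:
    """Load SBML (.xml/.sbml) or the TSV dialect (pass the ``.S.tsv`` path
    or its prefix)."""
    p = str(path)
    if p.endswith(".S.tsv"):
        return read_tsv(p[: -len(".S.tsv")])
    if p.endswith((".xml", ".sbml")):
        return read_sbml(p)
    if Path(p + ".S.tsv").exists():
        return read_tsv(p)
    return read_sbml(p)


def run_pipeline(
    net: StoichiometricNetwork,
    config: RunConfig | None = None,
    controller=None,
) -> PipelineResult:
    """Preprocess, run the selection rounds, post-process, score.

    Preprocessing marks structural externals (single pass) and applies the
    connectivity-threshold / explicit-list policy.  The efficacy N is the
    internal-metabolite count after structural detection but before any
    algorithmic reclassification, and the null-space validation compares
    that same full internal matrix against the final subnets.
    """
    config = config or RunConfig()
    work = net.copy()
    structural = detect_structural_externals(work) if config.structural_pass else set()
    n_internal_initial = len(work.internal_ids())
    baseline = work.copy()  # classification against which efficacy/nullspace judge
    policy_delta = apply_externals_policy(work, config.policy())

    if controller is None and config.interactive:
        controller = InteractiveController()
    partition, _ = run_rounds(work, config.separators, controller)
    partition.reincorporable |= policy_delta
    postprocess.postprocess_partition(work, partition, config.separators)

    sizes = partition.sizes()
    eff = (
        metrics.efficacy(sizes, n_internal_initial)
        if sizes and n_internal_initial >= 2
        else None
    )
    ns = metrics.nullspace_activity(baseline, partition)
    return PipelineResult(
        partition=partition,
        structural_externals=structural,
        policy_externals=policy_delta,
        n_internal_initial=n_internal_initial,
        efficacy=eff,
        nullspace=ns,
    )


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------


def write_outputs(
    net: StoichiometricNetwork, result: PipelineResult, outdir: str | Path
) -> None:
    """Per-subnet SBML files, a partition summary TSV, and JSON reports."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    part = result.partition
    rows = []
    for k, sn in enumerate(part.subnets):
        write_subnet(
            net,
            sn.internal_metabolites,
            sn.reactions,
            outdir / f"subnet_{k:02d}.xml",
            model_id=f"subnet_{k:02d}",
        )
        rows.append(
            {
                "block": k,
                "internal_count": len(sn.internal_metabolites),
                "reaction_count": len(sn.reactions),
                "externals": ";".join(sorted(sn.externals)),
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "partition_summary.tsv", sep="\t", index=False)

    with open(outdir / "rounds.jsonl", "w") as fh:
        for st in part.rounds:
            fh.write(
                json.dumps(
                    {
                        "round": st.round_number,
                        "Q": st.blocking.Q if st.blocking else None,
                        "cutoff": st.blocking.cutoff if st.blocking else None,
                        "n_blocks": len(st.blocks),
                        "proposed": st.proposed_separators,
                        "accepted": st.accepted,
                        "rejected": st.rejected,
                    }
                )
                + "\n"
            )
    report = {
        "separators": part.separators,
        "orphans": part.orphans,
        "dropped_reactions": part.dropped_reactions,
        "subnet_sizes": part.sizes(),
        "overlap_clean": part.overlaps.clean if part.overlaps else None,
        "efficacy": asdict(result.efficacy) if result.efficacy else None,
    }
    (outdir / "partition.json").write_text(json.dumps(report, indent=2, sort_keys=True))


def export_heatmap(matrix: np.ndarray, path: str | Path, cmap: str = "gray_r") -> None:
    """Grey-scale heatmap of a blocking/DAG matrix, with a TSV twin."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    path = Path(path)
    pd.DataFrame(matrix).to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(matrix, cmap=cmap, vmin=0, vmax=max(1.0, float(np.max(matrix))))
    ax.set_xlabel("sinks")
    ax.set_ylabel("sources")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
def main():
    """Split stoichiometric networks into coherent subnetworks."""


@main.command("split")
@click.argument("input_path", type=click.Path(exists=True))
@click.option("--threshold", type=int, default=8, show_default=True)
@click.option("--externals-file", type=click.Path(exists=True), default=None)
@click.option("--force-external", multiple=True)
@click.option("--force-internal", multiple=True)
@click.option("--veto", multiple=True)
@click.option("--max-rounds", type=int, default=50, show_default=True)
@click.option("--target-block-size", type=int, default=None)
@click.option("--interactive", is_flag=True)
@click.option("--outdir", type=click.Path(), default="netsplitter_out", show_default=True)
def cli_split(
    input_path,
    threshold,
    externals_file,
    force_external,
    force_internal,
    veto,
    max_rounds,
    target_block_size,
    interactive,
    outdir,
):
    """Run the full pipeline on a network and write subnet files."""
    net = load_network(input_path)
    force_ext = list(force_external)
    if externals_file:
        force_ext += read_externals_list(externals_file)
    config = RunConfig(
        connectivity_threshold=threshold,
        force_external=force_ext,
        force_internal=list(force_internal),
        separators=SeparatorConfig(
            max_rounds=max_rounds,
            target_max_block_size=target_block_size,
            veto=set(veto),
        ),
        interactive=interactive,
    )
    result = run_pipeline(net, config)
    write_outputs(net, result, outdir)
    part = result.partition
    click.echo(
        f"{len(part.subnets)} subnets "
        f"(sizes {sorted(part.sizes(), reverse=True)}), "
        f"{len(part.separators)} separators kept: {part.separators}"
    )
    if result.efficacy:
        click.echo(f"efficacy E = {result.efficacy.E:.1f}% (p = {result.efficacy.p:.2f})")


@main.command("dag")
@click.argument("input_path", type=click.Path(exists=True))
@click.option("--threshold", type=int, default=None)
@click.option("--structural/--no-structural", default=False, show_default=True,
              help="remove structural externals before the walk")
@click.option("--outdir", type=click.Path(), default="netsplitter_out", show_default=True)
@click.option("--heatmap/--no-heatmap", default=False)
def cli_dag(input_path, threshold, structural, outdir, heatmap):
    """Export P_inf and the truncated DAG matrix as TSV (optionally PNG)."""
    import pandas as pd

    net = load_network(input_path)
    if structural:
        detect_structural_externals(net)
    if threshold is not None:
        apply_externals_policy(net, ExternalsPolicy(connectivity_threshold=threshold))
    adj = build_adjacency(net)
    walk = converge_dag(build_transition(adj), adj.internal_index)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        walk.Pinf, index=walk.internal_index, columns=walk.internal_index
    ).to_csv(out / "Pinf.tsv", sep="\t")
    pd.DataFrame(walk.truncated, index=walk.sources, columns=walk.sinks).to_csv(
        out / "truncated.tsv", sep="\t"
    )
    if heatmap:
        export_heatmap(walk.truncated, out / "truncated.png")
    click.echo(
        f"{len(walk.internal_index)} internals: "
        f"{len(walk.sinks)} sinks, {len(walk.sources)} sources"
    )


@main.command("efficacy")
@click.option("--sizes", required=True, help="comma-separated subnet sizes")
@click.option("--n", "n_total", type=int, required=True, help="internal node count N")
@click.option("--p", type=float, default=None, help="effort exponent (default 0.25*sqrt(N))")
@click.option("--weight", type=click.Choice(["1/k", "1"]), default="1/k", show_default=True)
def cli_efficacy(sizes, n_total, p, weight):
    """Score a partitioning given its subnet sizes."""
    size_list = [float(s) for s in sizes.split(",") if s.strip()]
    rep = metrics.efficacy(size_list, n_total, p, weight_mode=weight)
    click.echo(
        f"E = {rep.E:.1f}%  (k={rep.k}, p={rep.p:.3g}, F={rep.F:.4g}, "
        f"range [{rep.F_lower:.4g}, {rep.F_upper:.4g}])"
    )


@main.command("validate")
@click.argument("input_path", type=click.Path(exists=True))
@click.option("--out", type=click.Path(), default=None)
def cli_validate(input_path, out):
    """Null-space activity report for the full network."""
    net = load_network(input_path)
    detect_structural_externals(net)
    rep = metrics.nullspace_activity(net)
    payload = {
        "n_reactions": net.n_reactions,
        "n_active": len(rep.active_full),
        "inactive": sorted(rep.inactive_full),
    }
    text = json.dumps(payload, indent=2)
    if out:
        Path(out).write_text(text)
    click.echo(text)


@main.command("synth")
@click.option("--modules", type=int, default=2, show_default=True)
@click.option("--size", type=int, default=10, show_default=True)
@click.option("--bridges", type=int, default=1, show_default=True)
@click.option("--currency", type=int, default=2, show_default=True)
@click.option("--topology", type=click.Choice(["linear", "branched"]), default="linear")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True, help="output TSV prefix")
def cli_synth(modules, size, bridges, currency, topology, seed, out):
    """Generate a planted-module fixture network (TSV + ground-truth JSON)."""
    spec = synthetic.SyntheticSpec(
        module_count=modules,
        module_size=size,
        bridges_per_pair=bridges,
        currency_count=currency,
        topology=topology,
        seed=seed,
    )
    net, truth = synthetic.generate_synthetic(spec)
    write_tsv(net, out)
    Path(str(out) + ".truth.json").write_text(
        json.dumps(
            {
                "modules": [sorted(m) for m in truth.modules],
                "bridges": truth.bridges,
                "currency": truth.currency,
                "boundary": truth.boundary,
            },
            indent=2,
        )
    )
    click.echo(f"{net.n_metabolites} metabolites x {net.n_reactions} reactions -> {out}.*")


if __name__ == "__main__":
    main()
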