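"""End-to-end orchestration of the subfamily-delineation analysis.

One configuration drives the stage sequence cluster -> anchor -> conserve ->
classify -> tree (-> superpose); every stage writes its TSV/Newick output
under the configured output directory and the run ends with a
machine-readable JSON report (config echo, input hashes, stage summaries).
All randomness is seeded, so a rerun with identical config and inputs is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify as classify_mod, cluster as cluster_mod
from . import csr as csr_mod, phylogeny, sequence_io, superpose as superpose_mod, synth


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 17
    simulate: bool = True
    benchmark_config: str | None = None  # None -> shipped default
    alignment: str | None = None  # real-data input (aligned FASTA)
    reference_id: str | None = None
    refmap: str | None = None  # TSV: logo_position, ungapped_index
    truth: str | None = None  # TSV: id, label (optional for real data)
    run_cluster: bool = False
    identity_threshold: float = 0.5
    bootstrap_replicates: int = 100
    margin_bits: float = 5.0
    prune_cutoff: float = 2.0
    superpose_a: str | None = None  # "path:chain"
    superpose_b: str | None = None
    domains_a: list[list[int]] | None = None
    domains_b: list[list[int]] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            if not self.alignment or not self.reference_id or not self.refmap:
                raise StageError(
                    "config",
                    "non-synthetic runs need alignment, reference_id and refmap",
                )
            for p in (self.alignment, self.refmap, self.truth):
                if p and not Path(p).exists():
                    raise StageError("config", f"input path {p} does not exist")


@dataclass
class RunReport:
    version: str
    config: dict
    input_hashes: dict[str, str]
    outputs: dict[str, str]
    summary: dict

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"
        )


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_refmap(path: str | Path) -> dict[int, int]:
    df = pd.read_csv(path, sep="\t")
    return {int(r.iloc[0]): int(r.iloc[1]) for _, r in df.iterrows()}


def write_refmap(refmap: Mapping[int, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(refmap.items()), columns=["logo_position", "ungapped_index"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reusable experiment helpers (shared by the pipeline, tests and the
# acceptance script)


def loo_accuracy(
    matrix: csr_mod.CsrMatrix,
    truth: Mapping[str, str],
    delta: float = 5.0,
    beta: float = 1.0,
) -> float:
    """Leave-one-out self-consistency: classify every row against profiles
    built without it; returns the fraction of rows whose decision equals
    their truth label."""
    correct = 0
    ids = matrix.ids()
    for sid in ids:
        profiles = classify_mod.profiles_from_matrix(
            matrix, dict(truth), beta=beta, exclude=sid
        )
        call = classify_mod.classify(profiles, matrix.rows[sid], sid, delta=delta)
        correct += call.decision == truth[sid]
    return correct / len(ids)


def clade_supports(
    tree: phylogeny.Tree, truth: Mapping[str, str]
) -> dict[str, int | None]:
    """Bootstrap support of each truth class's split, or None where the class
    is not monophyletic (or too small to form an internal split)."""
    out: dict[str, int | None] = {}
    leaves = set(tree.leaf_names())
    for label in sorted(set(truth.values())):
        clade = {sid for sid, lab in truth.items() if lab == label} & leaves
        if len(clade) < 2 or len(leaves) - len(clade) < 2:
            out[label] = None
            continue
        try:
            out[label] = tree.support_of(clade)
        except KeyError:
            out[label] = None
    return out


def conservation_report(
    matrix: csr_mod.CsrMatrix,
    truth: Mapping[str, str],
    fingerprints: Mapping[str, Sequence[csr_mod.Fingerprint]],
) -> pd.DataFrame:
    """Per-fingerprint conservation counts.

    Subfamily-specific fingerprints are counted on that subfamily's rows;
    the shared group on the union of the two novel subfamilies.
    """
    subsets: dict[str, list[str]] = {}
    for sid in matrix.ids():
        if sid in truth:
            subsets.setdefault(truth[sid], []).append(sid)
    rows = []
    for group, fps in fingerprints.items():
        if group == "shared":
            ids = subsets.get("GH13_48", []) + subsets.get("GH13_49", [])
        else:
            ids = subsets.get(group, [])
        if not ids:
            continue
        for fp in fps:
            stat = csr_mod.conservation_count(matrix, fp.as_spec(), ids)
            rows.append(
                {
                    "group": group,
                    "fingerprint": fp.label,
                    "positions": "+".join(str(p) for p, _, _ in fp.positions),
                    "count": stat.count,
                    "total": stat.total,
                    "fraction": stat.fraction,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


def run_delineation(config: PipelineConfig) -> RunReport:
    """Execute the configured stages; outputs land under config.output_dir."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    summary: dict = {}
    hashes: dict[str, str] = {}

    # ---- inputs -----------------------------------------------------------
    fingerprints: Mapping[str, Sequence[csr_mod.Fingerprint]]
    if config.simulate:
        cfg = synth.load_benchmark_config(config.benchmark_config)
        if config.benchmark_config:
            hashes["benchmark_config"] = _sha256(config.benchmark_config)
        bench = synth.make_benchmark(
            list(cfg["specs"].values()), cfg["n_per_class"], seed=config.seed
        )
        alignment = bench.alignment
        truth = bench.truth
        refmap = bench.refmap
        reference_id = alignment.records[0].id
        fingerprints = cfg["fingerprints"]
        fasta_path = out / "benchmark.fasta"
        sequence_io.write_fasta(bench.records, fasta_path)
        truth_path = out / "truth.tsv"
        pd.DataFrame(sorted(truth.items()), columns=["id", "label"]).to_csv(
            truth_path, sep="\t", index=False
        )
        write_refmap(refmap, out / "refmap.tsv")
        outputs["benchmark_fasta"] = str(fasta_path)
        outputs["truth"] = str(truth_path)
        outputs["refmap"] = str(out / "refmap.tsv")
    else:
        alignment = sequence_io.read_alignment(config.alignment)
        hashes["alignment"] = _sha256(config.alignment)
        refmap = read_refmap(config.refmap)
        hashes["refmap"] = _sha256(config.refmap)
        reference_id = config.reference_id
        truth = {}
        if config.truth:
            df = pd.read_csv(config.truth, sep="\t")
            truth = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
            hashes["truth"] = _sha256(config.truth)
        fingerprints = synth.load_benchmark_config(None)["fingerprints"]

    # ---- clustering -------------------------------------------------------
    if config.run_cluster:
        try:
            ungapped = [
                sequence_io.SequenceRecord(r.id, r.ungapped(), r.description)
                for r in alignment.records
            ]
            clusters = cluster_mod.greedy_cluster(ungapped, config.identity_threshold)
        except Exception as exc:  # noqa: BLE001
            raise StageError("cluster", str(exc)) from exc
        cl_path = out / "clusters.tsv"
        pd.DataFrame(
            [
                {
                    "member": m,
                    "centroid": c,
                    "identity": clusters.identities.get(m, float("nan")),
                }
                for m, c in sorted(clusters.membership.items())
            ]
        ).to_csv(cl_path, sep="\t", index=False)
        outputs["clusters"] = str(cl_path)
        summary["n_clusters"] = len(clusters.centroids)

    # ---- CSR anchoring + statistics --------------------------------------
    try:
        cmap = csr_mod.anchor_csr_columns(alignment, reference_id, refmap)
        matrix = csr_mod.extract_csr_block(alignment, cmap)
    except Exception as exc:  # noqa: BLE001
        raise StageError("csr", str(exc)) from exc
    pft = csr_mod.position_frequencies(matrix)
    sequence_io.write_tsv(pft.to_frame(), out / "pfm.tsv")
    sequence_io.write_tsv(csr_mod.make_logo_table(pft), out / "logo.tsv")
    outputs["pfm"] = str(out / "pfm.tsv")
    outputs["logo"] = str(out / "logo.tsv")
    if truth:
        cons = conservation_report(matrix, truth, fingerprints)
        sequence_io.write_tsv(cons, out / "conservation.tsv")
        outputs["conservation"] = str(out / "conservation.tsv")
        summary["conservation"] = {
            f"{r.group}:{r.fingerprint}": round(r.fraction, 4)
            for r in cons.itertuples()
        }

    # ---- classification ---------------------------------------------------
    if truth:
        try:
            profiles = classify_mod.profiles_from_matrix(matrix, dict(truth))
            calls = [
                classify_mod.classify(
                    profiles, matrix.rows[sid], sid, delta=config.margin_bits
                )
                for sid in matrix.ids()
            ]
        except Exception as exc:  # noqa: BLE001
            raise StageError("classify", str(exc)) from exc
        calls_path = out / "calls.tsv"
        pd.DataFrame(
            [
                {
                    "id": c.query_id,
                    "decision": c.decision,
                    "best": c.best,
                    "margin_bits": round(c.margin, 4),
                }
                for c in calls
            ]
        ).to_csv(calls_path, sep="\t", index=False)
        outputs["calls"] = str(calls_path)
        summary["classification_accuracy"] = sum(
            c.decision == truth[c.query_id] for c in calls
        ) / len(calls)

    # ---- phylogeny --------------------------------------------------------
    try:
        trimmed = phylogeny.trim_to_barrel(alignment, cmap)
        tree = phylogeny.bootstrap_support(
            trimmed, n_replicates=config.bootstrap_replicates, seed=config.seed
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("tree", str(exc)) from exc
    tree_path = out / "tree.nwk"
    sequence_io.write_newick(tree, tree_path)
    outputs["tree"] = str(tree_path)
    if truth:
        supports = clade_supports(tree, truth)
        summary["clade_supports"] = supports
        summary["n_monophyletic"] = sum(v is not None for v in supports.values())

    # ---- superposition ----------------------------------------------------
    if config.superpose_a and config.superpose_b:
        try:
            path_a, chain_a = config.superpose_a.rsplit(":", 1)
            path_b, chain_b = config.superpose_b.rsplit(":", 1)
            cs_a = sequence_io.read_ca_coordinates(path_a, chain_a)
            cs_b = sequence_io.read_ca_coordinates(path_b, chain_b)
            hashes["structure_a"] = _sha256(path_a)
            hashes["structure_b"] = _sha256(path_b)
            dom_a = [tuple(x) for x in config.domains_a] if config.domains_a else None
            dom_b = [tuple(x) for x in config.domains_b] if config.domains_b else None
            corr = superpose_mod.pair_residues(cs_a, cs_b, dom_a, dom_b)
            result = superpose_mod.iterative_prune_superpose(
                cs_a, cs_b, corr, cutoff=config.prune_cutoff
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("superpose", str(exc)) from exc
        sup_path = out / "superposition.tsv"
        pd.DataFrame(
            [
                {
                    "n_input": result.n_input_pairs,
                    "n_retained": result.n_retained_pairs,
                    "rmsd": round(result.rmsd, 4),
                    "iterations": result.iterations,
                    "cutoff": result.cutoff,
                }
            ]
        ).to_csv(sup_path, sep="\t", index=False)
        outputs["superposition"] = str(sup_path)
        summary["superposition"] = {
            "n_retained": result.n_retained_pairs,
            "rmsd": round(result.rmsd, 4),
        }

    report = RunReport(
        version=__version__,
        config=asdict(config),
        input_hashes=hashes,
        outputs=outputs,
        summary=summary,
    )
    report.write(out / "report.json")
    return report
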