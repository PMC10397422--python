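"""File formats, pipeline configuration, and the end-to-end run.

Formats are deliberately plain: 2-column TSV edge lists, 2-column TSV
SMILES tables, FASTA protein sequences, TSV/JSON outputs. The pipeline run
trains on the known interactions plus sampled negatives, scores every
remaining drug-target pair, and writes embeddings, depths, ranked
predictions and a manifest recording config, seeds and output checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .evaluation import SamplingPlan, compute_metrics, sample_negatives
from .features import (
    DrugFeatureConfig,
    FeatureMatrix,
    assemble_initial_features,
    encode_drug_structures,
    encode_protein_sequences,
    l2_normalize_rows,
    reduce_dimensionality,
)
from .hbin import Hbin, build_hbin
from .predictor import (
    GbdtConfig,
    call_interactions,
    make_pair_features,
    rank_candidates,
    train_classifier,
    PairDataset,
)
from .smoothing import NdlsConfig, smooth_all

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_edge_list",
    "read_molecule_table",
    "read_fasta",
    "write_edge_list",
    "write_molecule_table",
    "write_fasta",
    "write_embeddings",
    "read_embeddings",
    "load_hbin_from_files",
    "run_pipeline",
]


class PipelineConfig(BaseModel):
    """Declarative settings for an end-to-end run. Unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    edges: str
    smiles: str
    fasta: str
    output_dir: str = "dtismooth_out"
    r: float = Field(default=0.5, ge=0.0, le=1.0)
    epsilon: float = Field(default=1e-4, gt=0.0)
    k_max: int = Field(default=200, ge=1)
    d: int = Field(default=64, ge=1)
    n_bits: int = Field(default=1024, ge=1)
    radius: int = Field(default=2, ge=0)
    reducer: str = "autoencoder"
    epochs: int = Field(default=200, ge=1)
    n_trees: int = Field(default=500, ge=1)
    learning_rate: float = Field(default=0.1, gt=0.0)
    max_depth: int = Field(default=3, ge=1)
    sampling_ratio: int = Field(default=1, ge=1)
    n_folds: int = Field(default=10, ge=2)
    mask_test_edges: bool = True
    cutoff: float = Field(default=0.5, ge=0.0, le=1.0)
    top_n: int = Field(default=20, ge=1)
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_widths(self):
        if self.d > self.n_bits:
            raise ValueError(f"d={self.d} exceeds fingerprint width {self.n_bits}")
        if self.reducer not in ("autoencoder", "truncated-svd"):
            raise ValueError(f"unknown reducer {self.reducer!r}")
        return self


def read_edge_list(path) -> list[tuple[str, str]]:
    """Ordered unique (drug_id, target_id) pairs from a 2-column TSV.

    '#' comment lines and an optional header row are skipped; whitespace is
    trimmed; malformed lines are reported with their line number.
    """
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    first_data = True
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2 or not all(fields):
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            if first_data:
                first_data = False
                if fields[0].lower() in ("drug_id", "drug"):
                    continue
            pair = (fields[0], fields[1])
            if pair not in seen:
                seen.add(pair)
                pairs.append(pair)
    if not pairs:
        raise ValueError(f"{path}: no interactions found")
    return pairs


def read_molecule_table(path) -> dict[str, str]:
    """id -> SMILES from a 2-column TSV (optional header, '#' comments)."""
    table: dict[str, str] = {}
    first_data = True
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2 or not all(fields):
                raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
            if first_data:
                first_data = False
                if fields[0].lower() in ("drug_id", "drug", "id"):
                    continue
            drug_id, smiles = fields
            if drug_id in table:
                raise ValueError(f"{path}: duplicate drug id {drug_id!r}")
            table[drug_id] = smiles
    if not table:
        raise ValueError(f"{path}: no molecules found")
    return table


def read_fasta(path) -> dict[str, str]:
    """id -> uppercased sequence; header token up to first whitespace."""
    table: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in table:
            raise ValueError(f"{path}: duplicate sequence id {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty record {record.id!r}")
        table[record.id] = seq
    if not table:
        raise ValueError(f"{path}: no FASTA records found")
    return table


def write_edge_list(path, pairs: list[tuple[str, str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\ttarget_id\n")
        for drug_id, target_id in pairs:
            fh.write(f"{drug_id}\t{target_id}\n")


def write_molecule_table(path, table: dict[str, str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\tsmiles\n")
        for drug_id, smiles in table.items():
            fh.write(f"{drug_id}\t{smiles}\n")


def write_fasta(path, table: dict[str, str]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq_id, seq in table.items():
            fh.write(f">{seq_id}\n")
            for start in range(0, len(seq), 70):
                fh.write(seq[start : start + 70] + "\n")


def write_embeddings(path, node_ids: list[str], X: np.ndarray, depths=None) -> None:
    """TSV with node ids as row labels (optionally a depth column)."""
    df = pd.DataFrame(X, index=pd.Index(node_ids, name="node_id"))
    if depths is not None:
        df.insert(0, "depth", depths)
    df.to_csv(path, sep="\t")


def read_embeddings(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="node_id")


def load_hbin_from_files(edges_path, smiles_path, fasta_path):
    """Read the three inputs and build a consistent network.

    Node order follows the SMILES/FASTA tables (drugs first). Every node
    referenced by an edge must have features; nodes lacking them are
    reported together, since biomolecules without biological knowledge
    cannot be embedded.
    """
    pairs = read_edge_list(edges_path)
    smiles = read_molecule_table(smiles_path)
    seqs = read_fasta(fasta_path)
    missing_drugs = sorted({d for d, _ in pairs} - set(smiles))
    missing_targets = sorted({t for _, t in pairs} - set(seqs))
    if missing_drugs or missing_targets:
        raise ValueError(
            "nodes in the edge list lack features: "
            f"drugs {missing_drugs}, targets {missing_targets}"
        )
    hbin = build_hbin(list(smiles), list(seqs), pairs)
    return hbin, smiles, seqs


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def compute_initial_features(hbin: Hbin, smiles: dict, seqs: dict, cfg: PipelineConfig):
    drug_cfg = DrugFeatureConfig(
        n_bits=cfg.n_bits,
        radius=cfg.radius,
        d=cfg.d,
        reducer=cfg.reducer,
        seed=cfg.seed,
        epochs=cfg.epochs,
    )
    raw = encode_drug_structures([smiles[d] for d in hbin.catalog.drug_ids], drug_cfg)
    c_d = reduce_dimensionality(raw, drug_cfg)
    c_t = encode_protein_sequences([seqs[t] for t in hbin.catalog.target_ids])
    C = assemble_initial_features(c_d, c_t, hbin.catalog)
    # Common scale across node types; see l2_normalize_rows.
    return FeatureMatrix(values=l2_normalize_rows(C.values), catalog=hbin.catalog)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """End-to-end run: features -> C -> operator -> depths -> X -> GBDT -> scores.

    Trains on all known interactions plus ratio-sampled negatives, scores
    every remaining unknown drug-target pair, and writes embeddings,
    depths, ranked predictions, training metrics and a manifest to the
    output directory. Returns the manifest dictionary.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    hbin, smiles, seqs = load_hbin_from_files(cfg.edges, cfg.smiles, cfg.fasta)
    catalog = hbin.catalog
    logger.info(
        "network: %d drugs, %d targets, %d interactions",
        catalog.n_drugs, catalog.n_targets, hbin.n_edges,
    )

    C = compute_initial_features(hbin, smiles, seqs, cfg)
    ndls = NdlsConfig(epsilon=cfg.epsilon, k_max=cfg.k_max)
    emb, depths = smooth_all(hbin, C.values, ndls, r=cfg.r)

    node_ids = list(catalog.drug_ids) + list(catalog.target_ids)
    write_embeddings(out / "embeddings.tsv", node_ids, emb.X, depths.depths)

    positives = sorted(hbin.edges)
    negatives = sample_negatives(hbin, SamplingPlan(ratio=cfg.sampling_ratio, seed=cfg.seed))
    train_pairs = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    h = make_pair_features(emb.X, train_pairs, catalog.n_drugs)
    dataset = PairDataset(pairs=tuple(train_pairs), labels=labels, features=h)
    gbdt = GbdtConfig(
        n_trees=cfg.n_trees,
        learning_rate=cfg.learning_rate,
        max_depth=cfg.max_depth,
        seed=cfg.seed,
    )
    model = train_classifier(dataset, gbdt)
    train_metrics = compute_metrics(labels, model.score_pairs(h), cfg.cutoff)

    # Score every unknown pair (testing universe of the case-study protocol).
    known = set(train_pairs)
    unknown = [
        (i, catalog.n_drugs + j)
        for i in range(catalog.n_drugs)
        for j in range(catalog.n_targets)
        if (i, catalog.n_drugs + j) not in known
    ]
    pred_path = out / "predictions.tsv"
    if unknown:
        h_unknown = make_pair_features(emb.X, unknown, catalog.n_drugs)
        scores = model.score_pairs(h_unknown)
        calls = call_interactions(scores, cfg.cutoff)
        pair_ids = [(catalog.node_id(i), catalog.node_id(j)) for i, j in unknown]
        order = rank_candidates(scores, pair_ids, top_n=len(unknown))
        rows = [
            {
                "drug_id": pair_ids[k][0],
                "target_id": pair_ids[k][1],
                "score": scores[k],
                "call": int(calls[k]),
            }
            for k in order
        ]
        pd.DataFrame(rows).to_csv(pred_path, sep="\t", index=False)
    else:
        pd.DataFrame(columns=["drug_id", "target_id", "score", "call"]).to_csv(
            pred_path, sep="\t", index=False
        )

    metrics_path = out / "metrics.json"
    metrics_path.write_text(json.dumps(train_metrics.as_dict(), indent=2))

    manifest = {
        "config": cfg.model_dump(),
        "n_drugs": catalog.n_drugs,
        "n_targets": catalog.n_targets,
        "n_interactions": hbin.n_edges,
        "n_negatives": len(negatives),
        "depth_min": int(depths.depths.min()),
        "depth_max": int(depths.depths.max()),
        "n_truncated": int(depths.truncated.sum()),
        "outputs": {
            p.name: _sha256(p)
            for p in (out / "embeddings.tsv", pred_path, metrics_path)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
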