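"""Seedable synthetic fixtures: networks, disorder tracks, labelled pairs.

Every other module is testable without downloads through this generator.
It emulates the statistical structure the pipeline consumes — directed
signed Erdos-Renyi networks with a configured negative-edge fraction,
two-component disorder-score mixtures (so both well-folded, LCK-like
low-disorder proteins and genuinely disordered proteins occur), sparse
curated-region coverage, target/drug tables, and labelled neighbour-target
pair datasets with a planted, recoverable signal — not the degree
distribution or biology of any real signalling network.

All outputs are pure functions of :class:`SynthConfig` (byte-identical per
seed).  Default sizes mirror the scale of a realistic curated corpus:
about 880 labelled pairs of which about 38% are positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as _annotate
from .annotate import (DISORDER_SOURCES, DisorderRegionSet,
                       ProteinAnnotation, ResidueScoreTrack,
                       build_annotation_table)
from .features import Dataset, build_feature_table, extract_pairs
from .learn import node_centralities
from .motifs import SignedEdge, SignedNetwork, census_triangles

__all__ = [
    "SynthConfig",
    "synth_network",
    "synth_annotations",
    "synth_labelled_dataset",
    "write_mmcif",
    "write_workspace",
]


class SynthError(ValueError):
    pass


class FixtureTooSmallError(SynthError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic study conditions."""

    seed: int = 0
    n_nodes: int = 150
    edge_probability: float = 0.06
    negative_edge_fraction: float = 0.3
    n_networks: int = 3
    n_targets: int = 30
    n_idps: int = 40                      # DisProt-covered proteins
    #: Beta shape pairs for the low/high disorder mixture components and
    #: the fraction of proteins in the high-disorder component.
    disorder_low: tuple[float, float] = (2.0, 10.0)
    disorder_high: tuple[float, float] = (8.0, 3.0)
    high_disorder_fraction: float = 0.3
    min_length: int = 80
    max_length: int = 300
    signal_model: str = "none"            # none|motif_count|disorder_linear|mixed
    effect_feature: str = "n_unbalanced"  # feature carrying the motif_count signal
    label_noise_rate: float = 0.0
    n_labelled: int = 880
    positive_fraction: float = 332 / 880

    def __post_init__(self) -> None:
        for name in ("edge_probability", "negative_edge_fraction",
                     "high_disorder_fraction", "label_noise_rate",
                     "positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthError(f"{name} must be in [0,1], got {v}")
        if self.signal_model not in ("none", "motif_count",
                                     "disorder_linear", "mixed"):
            raise SynthError(f"unknown signal model {self.signal_model!r}")


def _node_ids(config: SynthConfig) -> list[str]:
    width = len(str(config.n_nodes))
    return [f"P{i:0{width}d}" for i in range(config.n_nodes)]


def synth_network(config: SynthConfig, index: int = 0) -> SignedNetwork:
    """Directed signed G(n, p) random graph, deterministic per (seed, index)."""
    rng = np.random.default_rng((config.seed, 101, index))
    ids = _node_ids(config)
    n = len(ids)
    mask = rng.random((n, n)) < config.edge_probability
    np.fill_diagonal(mask, False)
    negative = rng.random((n, n)) < config.negative_edge_fraction
    edges = [SignedEdge(ids[i], ids[j], -1 if negative[i, j] else 1)
             for i, j in zip(*np.nonzero(mask))]
    return SignedNetwork(name=f"synthnet{index}", edges=edges, nodes=ids)


def _mixture_mean(config: SynthConfig, rng: np.random.Generator,
                  n: int) -> np.ndarray:
    """Per-protein mean disorder level from the two-component mixture."""
    high = rng.random(n) < config.high_disorder_fraction
    a_lo, b_lo = config.disorder_low
    a_hi, b_hi = config.disorder_high
    mean = np.where(high, rng.beta(a_hi, b_hi, size=n),
                    rng.beta(a_lo, b_lo, size=n))
    return mean


def synth_annotations(config: SynthConfig,
                      positive_pairs: list[tuple[str, str]] | None = None,
                      ) -> dict:
    """Residue tracks, curated regions, target and biomarker tables.

    Returns a dict with keys ``plddt_tracks``, ``iupred_long_tracks``,
    ``iupred_short_tracks``, ``region_sets``, ``target_table``,
    ``biomarker_table``, ``target_ids`` and ``drug_targets``.  When
    ``positive_pairs`` is given, every planted positive (neighbour,
    target) pair's neighbour receives a predictive-biomarker row naming a
    drug of its target, so the labels round-trip through the standard
    label-assembly rule.
    """
    rng = np.random.default_rng((config.seed, 202))
    ids = _node_ids(config)
    n = len(ids)
    lengths = rng.integers(config.min_length, config.max_length + 1, size=n)
    disorder_level = _mixture_mean(config, rng, n)

    plddt, iup_long, iup_short, regions = {}, {}, {}, {}
    disprot_ids = set(rng.choice(ids, size=min(config.n_idps, n),
                                 replace=False))
    for pid, length, level in zip(ids, lengths, disorder_level):
        length = int(length)
        # per-residue noise around the protein's disorder level
        base = np.clip(level + rng.normal(0, 0.12, size=length), 0, 1)
        plddt[pid] = ResidueScoreTrack(pid, 100.0 * (1.0 - base))
        iup_long[pid] = ResidueScoreTrack(
            pid, np.clip(base + rng.normal(0, 0.05, size=length), 0, 1))
        iup_short[pid] = ResidueScoreTrack(
            pid, np.clip(base + rng.normal(0, 0.08, size=length), 0, 1))
        if pid in disprot_ids:
            n_dis = max(1, int(round(level * length)))
            start = int(rng.integers(1, length - n_dis + 2))
            regions[pid] = DisorderRegionSet(
                pid, length, [(start, start + n_dis - 1)])

    target_ids = sorted(rng.choice(ids, size=min(config.n_targets, n),
                                   replace=False))
    target_rows = []
    for tid in target_ids:
        modality = ("antibody" if rng.random() < 0.25 else "small_molecule")
        target_rows.append((tid, f"DRUG_{tid}", modality, "approved"))
    target_table = pd.DataFrame(
        target_rows,
        columns=["protein_id", "drug_id", "modality", "approval_status"])
    drug_targets = _annotate.drug_target_map(target_table)

    biomarker_rows = []
    if positive_pairs:
        for neighbour, target in sorted(set(positive_pairs)):
            biomarker_rows.append((neighbour, "predictive", f"DRUG_{target}"))
    # sprinkle unrelated prognostic annotations on a fifth of the proteome
    positive_neighbours = {n_ for n_, _ in (positive_pairs or [])}
    for pid in ids:
        if pid not in positive_neighbours and rng.random() < 0.2:
            biomarker_rows.append((pid, "prognostic", None))
    biomarker_table = pd.DataFrame(
        biomarker_rows, columns=["protein_id", "biomarker_type", "drug_id"])

    return {
        "plddt_tracks": plddt,
        "iupred_long_tracks": iup_long,
        "iupred_short_tracks": iup_short,
        "region_sets": regions,
        "target_table": target_table,
        "biomarker_table": biomarker_table,
        "target_ids": target_ids,
        "drug_targets": drug_targets,
    }


def _signal_score(config: SynthConfig, table: pd.DataFrame,
                  rng: np.random.Generator) -> np.ndarray:
    if config.signal_model == "none":
        return rng.random(len(table))
    if config.signal_model == "motif_count":
        return table[config.effect_feature].to_numpy(float)
    if config.signal_model == "disorder_linear":
        return table["neighbour_alphafold_content"].to_numpy(float)
    # mixed: standardised sum of the two
    a = table[config.effect_feature].to_numpy(float)
    b = table["neighbour_alphafold_content"].to_numpy(float)
    return _z(a) + _z(b)


def _z(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def synth_labelled_dataset(config: SynthConfig) -> tuple[Dataset, dict]:
    """End-to-end fixture: networks -> census -> features -> planted labels.

    Class 1 is planted by thresholding the configured signal score at the
    empirical quantile matching ``positive_fraction`` (for the
    ``motif_count`` model the label is therefore a deterministic function
    of one feature column, giving a separable dataset at zero noise);
    labels are then flipped independently at ``label_noise_rate``.  Pairs
    beyond ``n_labelled`` remain unlabelled.

    Returns the dataset and a ground-truth dict (threshold, pre-noise
    labels, flipped row indices, the annotation bundle and networks) for
    recovery tests.
    """
    rng = np.random.default_rng((config.seed, 303))
    networks = {f"synthnet{i}": synth_network(config, index=i)
                for i in range(config.n_networks)}
    motifs = {name: census_triangles(net) for name, net in networks.items()}

    bundle = synth_annotations(config)
    annotations = build_annotation_table(
        region_sets=bundle["region_sets"],
        plddt_tracks=bundle["plddt_tracks"],
        iupred_long_tracks=bundle["iupred_long_tracks"],
        iupred_short_tracks=bundle["iupred_short_tracks"],
        target_table=bundle["target_table"],
        biomarker_table=None)

    pairs = extract_pairs(motifs, annotations)
    if len(pairs) < 10:
        raise FixtureTooSmallError(
            f"only {len(pairs)} neighbour-target pairs generated; raise "
            "n_nodes or edge_probability")
    centralities = {name: node_centralities(net)
                    for name, net in networks.items()}
    dataset = build_feature_table(pairs, networks, motifs, annotations,
                                  centralities,
                                  provenance={"seed": config.seed,
                                              "signal": config.signal_model})

    table = dataset.table
    n_lab = min(config.n_labelled, len(table))
    labelled_idx = np.sort(rng.choice(len(table), size=n_lab, replace=False))
    score = _signal_score(config, table, rng)
    sub_scores = score[labelled_idx]
    # threshold on the signal so the label is a deterministic function of
    # it; among the attainable cut points pick the one whose positive
    # fraction is closest to the configured value (discrete signals such
    # as motif counts cannot hit the fraction exactly)
    candidates = np.unique(sub_scores)
    fractions = np.array([(sub_scores >= t).mean() for t in candidates])
    feasible = fractions < 1.0
    if not feasible.any():
        raise FixtureTooSmallError(
            "signal score is constant over the labelled pairs; no "
            "non-trivial label threshold exists")
    best = np.argmin(np.where(feasible,
                              np.abs(fractions - config.positive_fraction),
                              np.inf))
    threshold = float(candidates[best])
    true_labels = (sub_scores >= threshold).astype(float)

    flips = rng.random(n_lab) < config.label_noise_rate
    noisy = np.where(flips, 1.0 - true_labels, true_labels)
    labels = np.full(len(table), np.nan)
    labels[labelled_idx] = noisy
    table = table.copy()
    table["label"] = labels
    out = Dataset(table, list(dataset.feature_names),
                  dict(dataset.provenance))

    positive_pairs = [
        (table.iloc[i]["neighbour_id"], table.iloc[i]["target_id"])
        for i, lab in zip(labelled_idx, noisy) if lab == 1.0]
    bundle = synth_annotations(config, positive_pairs=positive_pairs)

    ground_truth = {
        "config": config,
        "threshold": threshold,
        "labelled_idx": labelled_idx,
        "true_labels": true_labels,
        "flipped": flips,
        "networks": networks,
        "motifs": motifs,
        "annotations": bundle,
    }
    return out, ground_truth


# ---------------------------------------------------------------------------
# file materialisation

MMCIF_HEADER = """\
data_{pid}
#
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
"""


def write_mmcif(path: str | Path, protein_id: str, plddt: np.ndarray,
                chain: str = "A") -> None:
    """Write a minimal mmCIF with one CA atom per residue.

    The per-residue pLDDT value is stored in the B-factor column, the
    layout used by predicted-structure archives.  Synthetic stand-in for
    a real predicted structure file.
    """
    lines = [MMCIF_HEADER.format(pid=protein_id)]
    for i, value in enumerate(plddt, start=1):
        x = 0.38 * i
        lines.append(
            f"ATOM {i} C CA . ALA {chain} 1 {i} {x:.3f} 0.000 0.000 "
            f"1.00 {value:.2f} {i} {chain}\n")
    lines.append("#\n")
    Path(path).write_text("".join(lines), encoding="utf-8")


def write_workspace(config: SynthConfig, outdir: str | Path,
                    with_structures: bool = True) -> dict[str, Path]:
    """Materialise a complete workspace of input files for the pipeline.

    Writes per-network signed edge lists, residue-score tables, curated
    region tables, target and biomarker tables, and (optionally) one
    mmCIF structure per protein.  Every file round-trips through the
    package's own readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, truth = synth_labelled_dataset(config)
    bundle = truth["annotations"]
    paths: dict[str, Path] = {}

    for name, net in truth["networks"].items():
        p = outdir / f"{name}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tsign\n")
            for e in sorted(net.edges):
                fh.write(f"{e.source}\t{e.target}\t{e.sign:+d}\n")
        paths[f"network:{name}"] = p

    for key, tracks in (("iupred_long", bundle["iupred_long_tracks"]),
                        ("iupred_short", bundle["iupred_short_tracks"])):
        p = outdir / f"{key}.tsv"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write("protein_id\tposition\tscore\n")
            for pid in sorted(tracks):
                for pos, s in enumerate(tracks[pid].scores, start=1):
                    fh.write(f"{pid}\t{pos}\t{s:.4f}\n")
        paths[key] = p

    p = outdir / "disprot_regions.tsv"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tlength\tstart\tend\n")
        for pid in sorted(bundle["region_sets"]):
            rs = bundle["region_sets"][pid]
            for start, end in rs.regions:
                fh.write(f"{pid}\t{rs.length}\t{start}\t{end}\n")
    paths["disprot_regions"] = p

    p = outdir / "targets.tsv"
    bundle["target_table"].to_csv(p, sep="\t", index=False)
    paths["targets"] = p

    p = outdir / "biomarkers.tsv"
    bundle["biomarker_table"].to_csv(p, sep="\t", index=False)
    paths["biomarkers"] = p

    if with_structures:
        struct_dir = outdir / "structures"
        struct_dir.mkdir(exist_ok=True)
        for pid, track in sorted(bundle["plddt_tracks"].items()):
            write_mmcif(struct_dir / f"{pid}.cif", pid, track.scores)
        paths["structures"] = struct_dir

    dataset.write_tsv(outdir / "dataset.tsv")
    paths["dataset"] = outdir / "dataset.tsv"
    return paths
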