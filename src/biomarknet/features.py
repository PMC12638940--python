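"""Per-pair feature vectors and training labels for neighbour-target pairs.

A *neighbour-target pair* is any protein that shares at least one triangle
motif with an approved drug-target protein, regardless of the sign and
direction of the connecting edges.  For every such ordered pair (the
target may itself serve as the neighbour of another target) a fixed-length
feature vector is assembled from:

* biological features — per-source disorder contents and mean scores of
  both proteins, with explicit missing indicators (curated disorder data
  is sparse; absence is information, not zero), the neighbour's own
  target status, and the drug-modality of the target;
* topological features — per-network participation flags, shared-triangle
  counts (total / unbalanced / cycle), the two directed edge signs
  between the proteins, aggregates over the third nodes of the shared
  triangles, and betweenness / bridging centralities of both proteins.

Training labels: class 1 when the neighbour is an annotated predictive
biomarker for a drug whose target list contains the paired target;
class 0 neighbours are drawn from proteins absent from the biomarker
annotation altogether, supplemented by seeded random draws from the
unlabelled pool when a dataset is too small.  Everything else stays
unlabelled and is scored, not trained on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import DISORDER_SOURCES, ProteinAnnotation
from .motifs import SignedNetwork, TriangleMotif, pair_triangle_participation

__all__ = [
    "Dataset",
    "extract_pairs",
    "build_feature_table",
    "assemble_training_labels",
    "scope_feature_names",
    "KEY_COLUMNS",
]

KEY_COLUMNS = ("neighbour_id", "target_id", "network")

MEAN_SCORE_SOURCES = ("alphafold", "iupred_long", "iupred_short")


class FeatureError(ValueError):
    pass


class PoolExhaustedError(FeatureError):
    pass


@dataclass
class Dataset:
    """Feature table plus metadata.

    ``table`` holds the key columns, the ``label`` column (1.0 / 0.0 /
    NaN for unlabelled) and one column per feature name.
    """

    table: pd.DataFrame
    feature_names: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dup = self.table.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            raise FeatureError("duplicated (neighbour, target, network) keys")

    @property
    def X(self) -> np.ndarray:
        return self.table[self.feature_names].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.table["label"].to_numpy(float)

    def labelled(self) -> "Dataset":
        mask = self.table["label"].notna()
        return Dataset(self.table[mask].reset_index(drop=True),
                       list(self.feature_names), dict(self.provenance))

    def unlabelled(self) -> "Dataset":
        mask = self.table["label"].isna()
        return Dataset(self.table[mask].reset_index(drop=True),
                       list(self.feature_names), dict(self.provenance))

    def restrict_network(self, network: str) -> "Dataset":
        mask = self.table["network"] == network
        return Dataset(self.table[mask].reset_index(drop=True),
                       list(self.feature_names), dict(self.provenance))

    def restrict_features(self, names: Sequence[str]) -> "Dataset":
        missing = set(names) - set(self.feature_names)
        if missing:
            raise FeatureError(f"unknown feature names: {sorted(missing)}")
        keep = [c for c in self.table.columns
                if c not in self.feature_names or c in set(names)]
        return Dataset(self.table[keep].copy(), [n for n in self.feature_names
                                                 if n in set(names)],
                       dict(self.provenance))

    def write_tsv(self, path, sidecar: bool = True) -> None:
        self.table.to_csv(path, sep="\t", index=False)
        if sidecar:
            with open(str(path) + ".json", "w", encoding="utf-8") as fh:
                json.dump({"feature_names": self.feature_names,
                           "provenance": self.provenance}, fh, indent=2,
                          default=str)

    @classmethod
    def read_tsv(cls, path) -> "Dataset":
        table = pd.read_csv(path, sep="\t",
                            dtype={c: str for c in KEY_COLUMNS})
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text(encoding="utf-8"))
            feature_names = meta["feature_names"]
            provenance = meta.get("provenance", {})
        else:
            feature_names = [c for c in table.columns
                             if c not in KEY_COLUMNS and c != "label"]
            provenance = {}
        if "label" not in table.columns:
            table["label"] = np.nan
        return cls(table, feature_names, provenance)


def extract_pairs(
    motifs_by_network: Mapping[str, Sequence[TriangleMotif]],
    annotations: Mapping[str, ProteinAnnotation],
) -> list[tuple[str, str, str]]:
    """All (neighbour, target, network) triples found in triangles.

    Every member of a triangle containing a target becomes that target's
    neighbour, regardless of edge sign/direction; two targets in one
    triangle yield both ordered pairs.
    """
    pairs: set[tuple[str, str, str]] = set()
    for net_name, motifs in motifs_by_network.items():
        for motif in motifs:
            targets = [m for m in motif.members
                       if m in annotations and annotations[m].is_target]
            for tgt in targets:
                for member in motif.members:
                    if member != tgt:
                        pairs.add((member, tgt, net_name))
    return sorted(pairs)


def _disorder_features(prefix: str, ann: ProteinAnnotation | None,
                       row: dict) -> None:
    for source in DISORDER_SOURCES:
        content = None if ann is None else ann.disorder_content.get(source)
        row[f"{prefix}_{source}_content"] = 0.0 if content is None else content
        row[f"{prefix}_{source}_missing"] = 1.0 if content is None else 0.0
    for source in MEAN_SCORE_SOURCES:
        mean = None if ann is None else ann.mean_score.get(source)
        row[f"{prefix}_{source}_mean"] = 0.0 if mean is None else mean


def build_feature_table(
    pairs: Sequence[tuple[str, str, str]],
    networks: Mapping[str, SignedNetwork],
    motifs_by_network: Mapping[str, Sequence[TriangleMotif]],
    annotations: Mapping[str, ProteinAnnotation],
    centralities: Mapping[str, Mapping[str, tuple[float, float]]],
    provenance: dict | None = None,
) -> Dataset:
    """Assemble the per-pair feature table (deterministic column order).

    ``centralities`` maps network -> node -> (betweenness,
    bridgeness_proxy), precomputed by the learning module.
    """
    network_names = sorted(networks)
    pair_index = set(pairs)
    rows: list[dict] = []
    for neighbour, target, net_name in sorted(pairs):
        net = networks[net_name]
        if neighbour not in net or target not in net:
            raise FeatureError(
                f"pair ({neighbour}, {target}) not in network {net_name}")
        part = pair_triangle_participation(
            net, (neighbour, target), motifs=list(motifs_by_network[net_name]))
        row: dict = {
            "neighbour_id": neighbour,
            "target_id": target,
            "network": net_name,
        }
        for other in network_names:
            row[f"in_net_{other}"] = float((neighbour, target, other)
                                           in pair_index)
        row["n_triangles"] = float(part.n_triangles)
        row["n_unbalanced"] = float(part.n_unbalanced)
        row["n_cycles"] = float(part.n_cycles)
        row["sign_nt"] = float(part.sign_nt)
        row["sign_tn"] = float(part.sign_tn)

        n_ann = annotations.get(neighbour)
        t_ann = annotations.get(target)
        row["neighbour_is_target"] = float(bool(n_ann and n_ann.is_target))
        modality = t_ann.drug_modality if t_ann else "none"
        row["target_modality_small_molecule"] = float(
            modality == "small_molecule")
        row["target_modality_antibody"] = float(modality == "antibody")

        _disorder_features("neighbour", n_ann, row)
        _disorder_features("target", t_ann, row)

        thirds = part.third_nodes
        third_anns = [annotations.get(x) for x in thirds]
        row["third_n_targets"] = float(sum(
            1 for a in third_anns if a and a.is_target))
        for source in DISORDER_SOURCES:
            row[f"third_n_idp_{source}"] = float(sum(
                1 for a in third_anns if a and a.is_idp(source)))
            contents = [a.disorder_content[source] for a in third_anns
                        if a and source in a.disorder_content]
            row[f"third_mean_disorder_{source}"] = (
                float(np.mean(contents)) if contents else 0.0)

        cent = centralities.get(net_name, {})
        nb, nbr = cent.get(neighbour, (0.0, 0.0))
        tb, tbr = cent.get(target, (0.0, 0.0))
        row["neighbour_betweenness"] = nb
        row["neighbour_bridgeness_proxy"] = nbr
        row["target_betweenness"] = tb
        row["target_bridgeness_proxy"] = tbr
        rows.append(row)

    table = pd.DataFrame(rows)
    feature_names = [c for c in table.columns if c not in KEY_COLUMNS]
    table["label"] = np.nan
    prov = dict(provenance or {})
    prov.setdefault("config_hash", hashlib.sha256(
        json.dumps(sorted(feature_names)).encode()).hexdigest()[:16])
    return Dataset(table, feature_names, prov)


def assemble_training_labels(
    dataset: Dataset,
    annotations: Mapping[str, ProteinAnnotation],
    drug_targets: Mapping[str, set[str]],
    negative_strategy: str = "non_biomarker_plus_random",
    negative_ratio: float = 548 / 332,
    seed: int = 0,
    overrides: Mapping[tuple[str, str], int] | None = None,
) -> Dataset:
    """Attach class labels to a feature table.

    Class 1: the neighbour carries a predictive-biomarker annotation for a
    drug whose target list contains the paired target.  Class 0: sampled
    from neighbours with no biomarker annotation of any type, topped up
    with (or, for the ``"random"`` strategy, drawn entirely from) seeded
    random draws from the remaining unlabelled pairs until the negative
    count reaches ``negative_ratio`` times the positive count.  Pairs with
    any other biomarker annotation stay unlabelled.  ``overrides`` maps
    (neighbour, target) to a forced 0/1 label, standing in for manual
    curation of the positive list.
    """
    if negative_strategy not in ("non_biomarker_plus_random", "random"):
        raise FeatureError(f"unknown negative strategy {negative_strategy!r}")
    overrides = dict(overrides or {})
    table = dataset.table.copy()
    labels = np.full(len(table), np.nan)
    eligible_negative = np.zeros(len(table), dtype=bool)

    for i, row in enumerate(table.itertuples()):
        key = (row.neighbour_id, row.target_id)
        if key in overrides:
            labels[i] = float(overrides[key])
            continue
        ann = annotations.get(row.neighbour_id)
        if ann is not None and any(
                row.target_id in drug_targets.get(d, ())
                for d in ann.predictive_for_drugs):
            labels[i] = 1.0
        elif ann is None or not ann.biomarker_flags:
            eligible_negative[i] = True

    n_pos = int(np.nansum(labels == 1.0))
    n_neg_wanted = int(round(negative_ratio * n_pos))
    rng = np.random.default_rng(seed)

    if negative_strategy == "random":
        pool = np.flatnonzero(np.isnan(labels))
    else:
        pool = np.flatnonzero(eligible_negative & np.isnan(labels))
    if negative_strategy == "non_biomarker_plus_random":
        if len(pool) >= n_neg_wanted:
            chosen = rng.choice(pool, size=n_neg_wanted, replace=False)
        else:
            extra_pool = np.flatnonzero(np.isnan(labels)
                                        & ~eligible_negative)
            n_extra = n_neg_wanted - len(pool)
            if n_extra > len(extra_pool):
                raise PoolExhaustedError(
                    f"need {n_neg_wanted} negatives, only "
                    f"{len(pool) + len(extra_pool)} candidate pairs")
            chosen = np.concatenate([
                pool, rng.choice(extra_pool, size=n_extra, replace=False)])
    else:
        if n_neg_wanted > len(pool):
            raise PoolExhaustedError(
                f"need {n_neg_wanted} negatives, only {len(pool)} unlabelled")
        chosen = rng.choice(pool, size=n_neg_wanted, replace=False)
    labels[np.sort(chosen)] = 0.0

    table["label"] = labels
    prov = dict(dataset.provenance)
    prov.update({"negative_strategy": negative_strategy,
                 "negative_ratio": negative_ratio, "label_seed": seed})
    return Dataset(table, list(dataset.feature_names), prov)


def scope_feature_names(feature_names: Sequence[str], scope: str) -> list[str]:
    """Feature subset for one disorder-annotation scope.

    ``scope`` is ``disprot``, ``alphafold``, ``iupred`` (both variants) or
    ``all``.  Non-disorder features are always retained; disorder columns
    of other sources are masked out.
    """
    if scope == "all":
        return list(feature_names)
    if scope == "iupred":
        keep_sources = {"iupred_long", "iupred_short"}
    elif scope in ("disprot", "alphafold"):
        keep_sources = {scope}
    else:
        raise FeatureError(f"unknown annotation scope {scope!r}")
    out = []
    for name in feature_names:
        source = next((s for s in DISORDER_SOURCES if s in name), None)
        if source is None or source in keep_sources:
            out.append(name)
    return out
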