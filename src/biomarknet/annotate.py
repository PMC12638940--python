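"""Per-protein disorder content and biomarker/target annotation records.

Disorder content — the fraction of a protein's residues that are
intrinsically disordered — is computed from three independent kinds of
evidence:

* curated disorder regions (DisProt-style 1-based inclusive residue
  ranges): covered residues / length;
* per-residue pLDDT confidence from predicted structures (0-100, read
  from the B-factor column of mmCIF files): fraction of residues
  strictly below 50;
* per-residue IUPred-style disorder propensity in [0, 1], long and short
  variants: fraction of residues strictly above 0.5.

Strict inequalities put threshold-value residues on the ordered side.
The thresholds are configurable; the defaults are the conventional ones.
Missing sources stay absent (never silently zero) — curated disorder
databases cover only a minority of the proteome, and downstream feature
construction encodes absence with an explicit missing indicator.

Target status (drug, modality) and biomarker-type flags (prognostic,
predisposing, diagnostic, predictive — the latter with the drug whose
response it predicts) are merged into one :class:`ProteinAnnotation`
record per protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ResidueScoreTrack",
    "DisorderRegionSet",
    "ProteinAnnotation",
    "disorder_content_from_plddt",
    "disorder_content_from_iupred",
    "disorder_content_from_regions",
    "extract_plddt_from_mmcif",
    "build_annotation_table",
    "load_region_table",
    "load_score_table",
    "load_target_table",
    "load_biomarker_table",
    "DISORDER_SOURCES",
]

DISORDER_SOURCES = ("disprot", "alphafold", "iupred_long", "iupred_short")

BIOMARKER_TYPES = ("prognostic", "predisposing", "diagnostic", "predictive")


class AnnotationError(ValueError):
    pass


class EmptyTrackError(AnnotationError):
    pass


class InvalidRegionError(AnnotationError):
    pass


class ModalityConflictError(AnnotationError):
    pass


@dataclass
class ResidueScoreTrack:
    """One real score per residue, 1-based positions."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    @property
    def length(self) -> int:
        return len(self.scores)


@dataclass
class DisorderRegionSet:
    """Curated disorder regions, stored merged and non-overlapping."""

    protein_id: str
    length: int
    regions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end in self.regions:
            if not (1 <= start <= end <= self.length):
                raise InvalidRegionError(
                    f"{self.protein_id}: region ({start},{end}) outside "
                    f"1..{self.length}")
        self.regions = _merge_regions(self.regions)


def _merge_regions(regions: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(regions):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


@dataclass
class ProteinAnnotation:
    """Disorder contents from up to four sources plus biomarker/target flags."""

    protein_id: str
    disorder_content: dict[str, float] = field(default_factory=dict)
    mean_score: dict[str, float] = field(default_factory=dict)
    is_target: bool = False
    drug_modality: str = "none"          # small_molecule / antibody / none
    drugs: list[str] = field(default_factory=list)
    biomarker_flags: set[str] = field(default_factory=set)
    predictive_for_drugs: list[str] = field(default_factory=list)

    def is_idp(self, source: str) -> bool:
        """IDP call under one annotation source's convention.

        DisProt membership itself marks a protein as an IDP; predicted
        sources call a protein disordered when the track mean crosses the
        conventional threshold (mean pLDDT < 50, mean IUPred > 0.5).
        """
        if source == "disprot":
            return "disprot" in self.disorder_content
        if source == "alphafold":
            return self.mean_score.get("alphafold", 100.0) < 50.0
        if source in ("iupred_long", "iupred_short"):
            return self.mean_score.get(source, 0.0) > 0.5
        raise AnnotationError(f"unknown disorder source {source!r}")


def disorder_content_from_plddt(track: ResidueScoreTrack,
                                threshold: float = 50.0,
                                ) -> tuple[float, float]:
    """Fraction of residues with pLDDT strictly below ``threshold``.

    Returns ``(disorder_content, mean_score)``.
    """
    if track.length == 0:
        raise EmptyTrackError(f"{track.protein_id}: empty pLDDT track")
    scores = track.scores
    return float(np.mean(scores < threshold)), float(scores.mean())


def disorder_content_from_iupred(track: ResidueScoreTrack,
                                 threshold: float = 0.5,
                                 ) -> tuple[float, float]:
    """Fraction of residues with IUPred score strictly above ``threshold``.

    Returns ``(disorder_content, mean_score)``.
    """
    if track.length == 0:
        raise EmptyTrackError(f"{track.protein_id}: empty IUPred track")
    scores = track.scores
    return float(np.mean(scores > threshold)), float(scores.mean())


def disorder_content_from_regions(regions: DisorderRegionSet) -> float:
    """Residues covered by merged curated regions, as a fraction of length."""
    covered = sum(end - start + 1 for start, end in regions.regions)
    return covered / regions.length


def extract_plddt_from_mmcif(path: str | Path) -> ResidueScoreTrack:
    """Per-residue pLDDT track from the B-factor column of an mmCIF file.

    One value per residue, taken from the CA atom when present and from
    the residue's first atom otherwise; residues ordered by chain then
    sequence number.  Multi-chain files are concatenated in chain order.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if not st or len(st) == 0:
        raise AnnotationError(f"{path}: no models in structure")
    values: list[float] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            if len(residue) == 0:
                continue
            ca = residue.find_atom("CA", "*")
            atom = ca if ca is not None else residue[0]
            values.append(atom.b_iso)
    if not values:
        raise AnnotationError(f"{path}: no atom records found")
    return ResidueScoreTrack(protein_id=path.stem, scores=np.array(values))


# ---------------------------------------------------------------------------
# tabular readers

def load_region_table(path) -> dict[str, DisorderRegionSet]:
    """TSV ``protein_id, length, start, end`` (one row per region)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["protein_id", "length", "start", "end"],
                     header=0 if _has_header(path) else None)
    out: dict[str, DisorderRegionSet] = {}
    for pid, group in df.groupby("protein_id", sort=True):
        length = int(group["length"].iloc[0])
        regions = [(int(r.start), int(r.end)) for r in group.itertuples()]
        out[str(pid)] = DisorderRegionSet(str(pid), length, regions)
    return out


def load_score_table(path) -> dict[str, ResidueScoreTrack]:
    """TSV ``protein_id, position, score`` with 1-based positions."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["protein_id", "position", "score"],
                     header=0 if _has_header(path) else None)
    out: dict[str, ResidueScoreTrack] = {}
    for pid, group in df.groupby("protein_id", sort=True):
        group = group.sort_values("position")
        out[str(pid)] = ResidueScoreTrack(str(pid),
                                          group["score"].to_numpy(float))
    return out


def load_target_table(path) -> pd.DataFrame:
    """TSV ``protein_id, drug_id, modality, approval_status``."""
    return pd.read_csv(
        path, sep="\t", comment="#",
        names=["protein_id", "drug_id", "modality", "approval_status"],
        header=0 if _has_header(path) else None, dtype=str)


def load_biomarker_table(path) -> pd.DataFrame:
    """TSV ``protein_id, biomarker_type, drug_id`` (drug only for predictive)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["protein_id", "biomarker_type", "drug_id"],
                     header=0 if _has_header(path) else None, dtype=str)
    return df


def _has_header(path) -> bool:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return first.lower().startswith("protein_id")


# ---------------------------------------------------------------------------

def build_annotation_table(
    region_sets: Mapping[str, DisorderRegionSet] | None = None,
    plddt_tracks: Mapping[str, ResidueScoreTrack] | None = None,
    iupred_long_tracks: Mapping[str, ResidueScoreTrack] | None = None,
    iupred_short_tracks: Mapping[str, ResidueScoreTrack] | None = None,
    target_table: pd.DataFrame | None = None,
    biomarker_table: pd.DataFrame | None = None,
    plddt_threshold: float = 50.0,
    iupred_threshold: float = 0.5,
) -> dict[str, ProteinAnnotation]:
    """Merge disorder sources and biomarker/target tables per protein.

    One record is produced for every protein mentioned in any input; a
    source that does not cover a protein leaves the corresponding
    disorder field absent.  A drug annotated with conflicting modalities
    raises :class:`ModalityConflictError`.
    """
    region_sets = region_sets or {}
    plddt_tracks = plddt_tracks or {}
    iupred_long_tracks = iupred_long_tracks or {}
    iupred_short_tracks = iupred_short_tracks or {}

    ids: set[str] = set()
    ids.update(region_sets, plddt_tracks, iupred_long_tracks,
               iupred_short_tracks)
    if target_table is not None:
        ids.update(target_table["protein_id"])
    if biomarker_table is not None:
        ids.update(biomarker_table["protein_id"])

    records = {pid: ProteinAnnotation(pid) for pid in sorted(ids)}

    for pid, regset in region_sets.items():
        records[pid].disorder_content["disprot"] = \
            disorder_content_from_regions(regset)
    for pid, track in plddt_tracks.items():
        content, mean = disorder_content_from_plddt(track, plddt_threshold)
        records[pid].disorder_content["alphafold"] = content
        records[pid].mean_score["alphafold"] = mean
    for source, tracks in (("iupred_long", iupred_long_tracks),
                           ("iupred_short", iupred_short_tracks)):
        for pid, track in tracks.items():
            content, mean = disorder_content_from_iupred(track,
                                                         iupred_threshold)
            records[pid].disorder_content[source] = content
            records[pid].mean_score[source] = mean

    if target_table is not None:
        modality_by_drug: dict[str, str] = {}
        for row in target_table.itertuples():
            modality = str(row.modality)
            prev = modality_by_drug.setdefault(str(row.drug_id), modality)
            if prev != modality:
                raise ModalityConflictError(
                    f"drug {row.drug_id}: conflicting modalities "
                    f"{prev!r} vs {modality!r}")
            rec = records[str(row.protein_id)]
            rec.is_target = True
            if str(row.drug_id) not in rec.drugs:
                rec.drugs.append(str(row.drug_id))
            # antibody wins if a protein is hit by drugs of mixed modality;
            # the per-drug modality stays available via the drug map
            if rec.drug_modality == "none":
                rec.drug_modality = modality
            elif rec.drug_modality != modality:
                rec.drug_modality = "antibody"

    if biomarker_table is not None:
        for row in biomarker_table.itertuples():
            btype = str(row.biomarker_type).lower()
            if btype not in BIOMARKER_TYPES:
                raise AnnotationError(f"unknown biomarker type {btype!r}")
            rec = records[str(row.protein_id)]
            rec.biomarker_flags.add(btype)
            if btype == "predictive":
                drug = getattr(row, "drug_id", None)
                if drug is None or pd.isna(drug):
                    raise AnnotationError(
                        f"{row.protein_id}: predictive row lacks a drug id")
                if str(drug) not in rec.predictive_for_drugs:
                    rec.predictive_for_drugs.append(str(drug))

    return records


def drug_target_map(target_table: pd.DataFrame) -> dict[str, set[str]]:
    """drug_id -> set of protein ids the drug targets."""
    out: dict[str, set[str]] = {}
    for row in target_table.itertuples():
        out.setdefault(str(row.drug_id), set()).add(str(row.protein_id))
    return out
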