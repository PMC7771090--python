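"""Protein localization classes, chromosomal clusters and intron labels.

Globins sort into three cellular fates: *extracellular* (N-terminal secretion
signal; the subunits of giant annelid hemoglobins), *membrane* (dual
N-terminal acylation, i.e. a myristoylation site and a palmitoylation site
close together near the N-terminus) and *cytoplasmic* (neither).  Predictions
normally come from external predictor tables; a sequence-only fallback
heuristic is provided for fixtures without tables and is clearly second-rate.

Gene loci (GFF3 gene lines, 1-based inclusive coordinates) are grouped into
single-linkage clusters per scaffold, and intron positions are reported in
globin helix coordinates (helix letter A-H + residue index + phase), the
standard way conserved globin intron positions such as B12.2 and G7.0 are
written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd


class AnnotationError(ValueError):
    pass


LOCALIZATIONS = ("extracellular", "membrane", "cytoplasmic")

HYDROPHOBIC = set("AILMFVWC")


@dataclass
class FeaturePrediction:
    """Signal/acylation evidence for one gene (1-based residue indices)."""

    gene_id: str
    signal_peptide: bool = False
    myristoylation_sites: Tuple[int, ...] = ()
    palmitoylation_sites: Tuple[int, ...] = ()
    source: str = "external"  # external | fallback


def classify_localization(
    pred: FeaturePrediction, window: int = 25, max_gap: int = 10
) -> str:
    """Three-way localization call; extracellular takes precedence.

    membrane requires *both* a myristoylation and a palmitoylation site, both
    within the N-terminal ``window`` residues and within ``max_gap`` residues
    of each other ("closely located" dual acylation).
    """
    if pred.signal_peptide:
        return "extracellular"
    myr = [p for p in pred.myristoylation_sites if p <= window]
    palm = [p for p in pred.palmitoylation_sites if p <= window]
    for m in myr:
        for p in palm:
            if abs(m - p) <= max_gap:
                return "membrane"
    return "cytoplasmic"


def fallback_signal_heuristic(seq: str) -> bool:
    """Crude secretion-signal detector: within the first 30 residues, a run
    of >= 8 consecutive hydrophobic residues (AILMFVWC) starting after 1-5
    N-terminal residues.  A stand-in for real predictors; never used when an
    external predictor table is available."""
    head = seq[:30]
    run_start = None
    run_len = 0
    for i, aa in enumerate(head):
        if aa in HYDROPHOBIC:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len >= 8 and run_start is not None and 1 <= run_start <= 5:
                return True
        else:
            run_len = 0
    return False


def fallback_acylation_heuristic(seq: str) -> Tuple[Tuple[int, ...], Tuple[int, ...]]:
    """Crude dual-acylation detector: an N-terminal Met-Gly start (Gly-2
    myristoylation motif) plus a cysteine in the first 10 residues as the
    candidate palmitoylation site.  Returns (myr_sites, palm_sites),
    1-based."""
    myr: Tuple[int, ...] = ()
    if len(seq) >= 2 and seq[0] == "M" and seq[1] == "G":
        myr = (2,)
    palm = tuple(i + 1 for i, aa in enumerate(seq[:10]) if aa == "C")
    return myr, palm


def predict_features_fallback(gene_id: str, seq: str) -> FeaturePrediction:
    myr, palm = fallback_acylation_heuristic(seq)
    return FeaturePrediction(
        gene_id=gene_id,
        signal_peptide=fallback_signal_heuristic(seq),
        myristoylation_sites=myr,
        palmitoylation_sites=palm,
        source="fallback",
    )


def read_predictor_table(path) -> Dict[str, FeaturePrediction]:
    """TSV columns: gene, signal_peptide, myr_sites, palm_sites[, source];
    site lists are comma-separated 1-based indices."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    preds: Dict[str, FeaturePrediction] = {}
    for _, row in df.iterrows():
        preds[row["gene"]] = FeaturePrediction(
            gene_id=row["gene"],
            signal_peptide=str(row["signal_peptide"]).strip().lower()
            in {"true", "1", "yes"},
            myristoylation_sites=_parse_sites(row.get("myr_sites", "")),
            palmitoylation_sites=_parse_sites(row.get("palm_sites", "")),
            source=row.get("source", "external") or "external",
        )
    return preds


def _parse_sites(text: str) -> Tuple[int, ...]:
    text = str(text).strip()
    if not text:
        return ()
    return tuple(int(x) for x in text.split(",") if x.strip())


# ---------------------------------------------------------------------------
# Gene loci and clusters


@dataclass(frozen=True)
class LocusRecord:
    """A gene locus in GFF3 conventions (1-based, inclusive)."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")

    def interval(self) -> Tuple[int, int]:
        """Half-open 0-based interval for internal arithmetic."""
        return self.start - 1, self.end

    def overlaps(self, other: "LocusRecord") -> bool:
        if self.scaffold != other.scaffold:
            return False
        a0, a1 = self.interval()
        b0, b1 = other.interval()
        return a0 < b1 and b0 < a1


@dataclass
class GeneCluster:
    scaffold: str
    members: List[LocusRecord] = field(default_factory=list)  # ordered by start
    overlap_pairs: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def member_ids(self) -> List[str]:
        return [m.gene_id for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


def map_gene_clusters(
    loci: Sequence[LocusRecord], max_distance: int = 50_000
) -> List[GeneCluster]:
    """Single-linkage clustering of loci per scaffold: neighbours whose
    inter-gene gap is <= ``max_distance`` join the same cluster; singletons
    are returned as clusters of size one.  Input order does not matter."""
    by_scaffold: Dict[str, List[LocusRecord]] = {}
    for locus in loci:
        by_scaffold.setdefault(locus.scaffold, []).append(locus)
    clusters: List[GeneCluster] = []
    for scaffold in sorted(by_scaffold):
        members = sorted(by_scaffold[scaffold], key=lambda l: (l.start, l.end, l.gene_id))
        current: List[LocusRecord] = []
        max_end = None
        for locus in members:
            if max_end is not None and (locus.start - 1) - max_end > max_distance:
                clusters.append(_finish_cluster(scaffold, current))
                current = []
                max_end = None
            current.append(locus)
            max_end = locus.end if max_end is None else max(max_end, locus.end)
        if current:
            clusters.append(_finish_cluster(scaffold, current))
    return clusters


def _finish_cluster(scaffold: str, members: List[LocusRecord]) -> GeneCluster:
    overlaps = [
        (a.gene_id, b.gene_id)
        for i, a in enumerate(members)
        for b in members[i + 1 :]
        if a.overlaps(b)
    ]
    return GeneCluster(scaffold=scaffold, members=list(members), overlap_pairs=overlaps)


def read_gff3_loci(path) -> List[LocusRecord]:
    """Read gene lines from a GFF3 file (feature type ``gene``, ID attribute)."""
    loci = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9 or fields[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        )
        loci.append(
            LocusRecord(
                gene_id=attrs.get("ID", fields[8]),
                scaffold=fields[0],
                start=int(fields[3]),
                end=int(fields[4]),
                strand=fields[6],
            )
        )
    return loci


# ---------------------------------------------------------------------------
# Intron labels in helix coordinates


@dataclass(frozen=True)
class IntronLabel:
    gene_id: str
    helix: str  # single helix letter A-H, or a flanking pair such as "EF"
    residue_index: int  # 1-based within the helix / interhelical segment
    phase: int  # 0, 1 or 2

    def __str__(self) -> str:
        return f"{self.helix}{self.residue_index}.{self.phase}"


#: Helix track of the 150-residue template: alignment column ranges (0-based,
#: half-open) for the eight helices of the globin fold.
DEFAULT_HELIX_RANGES: Dict[str, Tuple[int, int]] = {
    "A": (3, 19),
    "B": (20, 36),
    "C": (36, 43),
    "D": (51, 58),
    "E": (58, 78),
    "F": (86, 96),
    "G": (100, 119),
    "H": (124, 146),
}


def helix_track_from_ranges(
    ranges: Dict[str, Tuple[int, int]], length: int
) -> List[Tuple[str, int]]:
    """Expand helix ranges into a per-column track of (segment, index).

    Columns outside every helix are labelled by the flanking helix pair
    (e.g. ``EF``), ``NA`` before helix A and ``HC`` after helix H, with
    1-based indices restarting in each segment.
    """
    order = sorted(ranges.items(), key=lambda kv: kv[1][0])
    track: List[Tuple[str, int]] = []
    col = 0
    prev_letter = None
    for letter, (start, end) in order:
        seg = f"{prev_letter}{letter}" if prev_letter else "NA"
        idx = 1
        while col < start:
            track.append((seg, idx))
            idx += 1
            col += 1
        idx = 1
        while col < end and col < length:
            track.append((letter, idx))
            idx += 1
            col += 1
        prev_letter = letter
    seg = f"{prev_letter}C" if prev_letter else "NA"
    idx = 1
    while col < length:
        track.append((seg, idx))
        idx += 1
        col += 1
    return track


def label_intron(
    position_in_alignment: int,
    phase: int,
    helix_track: Sequence[Tuple[str, int]],
    gene_id: str = "?",
) -> IntronLabel:
    """Label an intron by the helix coordinate of its alignment column
    (0-based) and its phase."""
    if phase not in (0, 1, 2):
        raise AnnotationError(f"intron phase must be 0, 1 or 2, got {phase}")
    if not 0 <= position_in_alignment < len(helix_track):
        raise AnnotationError(
            f"alignment position {position_in_alignment} outside track of "
            f"length {len(helix_track)}"
        )
    helix, idx = helix_track[position_in_alignment]
    return IntronLabel(gene_id=gene_id, helix=helix, residue_index=idx, phase=phase)


# ---------------------------------------------------------------------------
# Whole-repertoire annotation


def annotate_localizations(
    sequences: Dict[str, str],
    predictions: Optional[Dict[str, FeaturePrediction]] = None,
    window: int = 25,
    max_gap: int = 10,
) -> pd.DataFrame:
    """Localize every gene; external predictions are used where available and
    the fallback heuristics fill the gaps.  Total: every gene gets exactly
    one label."""
    rows = []
    for gene in sorted(sequences):
        pred = (predictions or {}).get(gene)
        if pred is None:
            pred = predict_features_fallback(gene, sequences[gene])
        rows.append(
            (gene, classify_localization(pred, window=window, max_gap=max_gap), pred.source)
        )
    return pd.DataFrame(rows, columns=["gene", "localization", "source"])
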