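"""Readers and writers for GO annotation (GAF) files, ortholog-cluster tables,
and evidence-weight configuration.

GO annotations arrive as GAF 2.x files (17-column TSV, ``!``-prefixed
comments), one line per (protein, term, evidence) record.  Each record carries
the evidence code that states how the annotation was made (direct assay,
sequence similarity, electronic inference, ...) and the date it was first
linked to the protein entry, which is what makes historical knownness queries
possible.  Ortholog/paralog clusters are plain 4-column TSV tables; evidence
weights are a YAML mapping from evidence code to a weight in [0, 1].
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio.UniProt import GOA

logger = logging.getLogger("unknome")

#: The 22 GO evidence codes recognised by the weight scheme.
EVIDENCE_CODES: frozenset[str] = frozenset(
    {
        "EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
        "ISS", "ISO", "ISA", "ISM", "IGC", "RCA",
        "TAS", "NAS", "IC", "ND", "IEA", "NR",
        "IRD", "IKR", "IBA", "IBD",
    }
)

#: Default evidence-code weights used for knownness scoring.  Experimental
#: codes score high (0.8), author statements higher still (TAS 0.9, curator
#: inference IC 1.0), sequence-based inference intermediate (0.5), and purely
#: electronic or uninformative codes zero.
DEFAULT_WEIGHTS: dict[str, float] = {
    "EXP": 0.8, "IDA": 0.8, "IPI": 0.8, "IMP": 0.8, "IGI": 0.8, "IEP": 0.8,
    "ISS": 0.5, "ISO": 0.5, "ISA": 0.5, "ISM": 0.5,
    "IGC": 0.3, "RCA": 0.6, "TAS": 0.9, "NAS": 0.6, "IC": 1.0,
    "ND": 0.0, "IEA": 0.0, "NR": 0.0,
    "IRD": 0.0, "IKR": 0.0, "IBA": 0.5, "IBD": 0.5,
}

ASPECTS: frozenset[str] = frozenset({"P", "F", "C"})

#: Human plus the 11 model-organism reference proteomes (NCBI taxon ids):
#: H. sapiens, A. thaliana, C. elegans, D. rerio, D. discoideum,
#: D. melanogaster, E. coli K-12, G. gallus, M. musculus, R. norvegicus,
#: S. cerevisiae, S. pombe.
REFERENCE_SPECIES: frozenset[str] = frozenset(
    {
        "9606", "3702", "6239", "7955", "44689", "7227",
        "83333", "9031", "10090", "10116", "559292", "284812",
    }
)


@dataclass(frozen=True)
class GoAnnotation:
    """A single GO annotation record.

    ``first_linked_date`` is the date the term was first linked to the
    protein entry; it may be ``None`` for records whose GAF row had no date
    (such records are usable for current-score queries but rejected by
    temporal ones).
    """

    protein_id: str
    go_term: str
    aspect: str
    evidence_code: str
    negated: bool = False
    first_linked_date: date | None = None
    reference: str | None = None
    taxon: str | None = None
    symbol: str | None = None

    def __post_init__(self) -> None:
        if self.evidence_code not in EVIDENCE_CODES:
            raise ValueError(
                f"unknown evidence code {self.evidence_code!r} for {self.protein_id}"
            )
        if self.aspect not in ASPECTS:
            raise ValueError(f"aspect must be one of P/F/C, got {self.aspect!r}")


@dataclass(frozen=True)
class WeightScheme:
    """Complete evidence-code -> weight map defining knownness.

    Every one of the 22 evidence codes must be present with a weight in
    [0, 1]; partial configurations are completed from :data:`DEFAULT_WEIGHTS`
    by :func:`read_weight_scheme`.
    """

    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    name: str = "default"

    def __post_init__(self) -> None:
        missing = EVIDENCE_CODES - set(self.weights)
        if missing:
            raise ValueError(f"weight scheme {self.name!r} missing codes: {sorted(missing)}")
        unknown = set(self.weights) - EVIDENCE_CODES
        if unknown:
            raise ValueError(f"weight scheme {self.name!r} has unknown codes: {sorted(unknown)}")
        for code, w in self.weights.items():
            if not 0.0 <= float(w) <= 1.0:
                raise ValueError(f"weight for {code} outside [0, 1]: {w}")

    def weight(self, evidence_code: str) -> float:
        return float(self.weights[evidence_code])


DEFAULT_SCHEME = WeightScheme()


@dataclass(frozen=True)
class Cluster:
    """An ortholog/paralog family: a cluster id plus species-tagged members."""

    cluster_id: str
    members: tuple[tuple[str, str, str], ...]  # (protein_id, taxon, symbol)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id} has no members")
        ids = [m[0] for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"cluster {self.cluster_id} has duplicate member protein ids")

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(m[0] for m in self.members)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(m[1] for m in self.members)


@dataclass(frozen=True)
class SpeciesSet:
    """Reference species (human + 11 model organisms) and an optional wider
    metazoan panel used for conservation filtering."""

    reference_species: frozenset[str] = REFERENCE_SPECIES
    metazoan_panel: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if len(self.reference_species) != 12:
            raise ValueError(
                f"reference species set must have 12 entries, got {len(self.reference_species)}"
            )


@dataclass(frozen=True)
class RejectedRow:
    line_number: int
    reason: str


@dataclass
class GafReadReport:
    """Outcome of reading a GAF file: accepted annotations plus per-row
    rejections, satisfying rows = annotations + rejections."""

    annotations: list[GoAnnotation]
    rejections: list[RejectedRow]
    n_data_rows: int


def _parse_gaf_date(raw: str) -> date | None:
    raw = raw.strip()
    if not raw:
        return None
    return datetime.strptime(raw, "%Y%m%d").date()


def _strip_taxon(raw: str) -> str:
    return raw.split(":", 1)[1] if ":" in raw else raw


def read_gaf_report(
    path: str | Path,
    taxon_filter: Iterable[str] | None = None,
    deduplicate: bool = True,
) -> GafReadReport:
    """Read a GAF 2.x file, validating each row.

    Malformed rows (bad date, unknown evidence code, wrong column count) are
    rejected individually with a logged reason; an unreadable file raises.
    Rows for taxa outside ``taxon_filter`` (if given) are dropped and counted
    as rejections, as are duplicate (protein, term, evidence, negated) rows
    when ``deduplicate`` is on, so no parseable row is ever silently lost.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")  # raises on unreadable file
    taxa = {_strip_taxon(t) for t in taxon_filter} if taxon_filter is not None else None

    annotations: list[GoAnnotation] = []
    rejections: list[RejectedRow] = []
    seen: set[tuple[str, str, str, bool]] = set()
    n_data_rows = 0

    header = "!gaf-version: 2.2\n"
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("!"):
            continue
        n_data_rows += 1
        ncols = len(line.split("\t"))
        if ncols < 15:
            rejections.append(RejectedRow(lineno, f"expected >=15 tab-separated columns, got {ncols}"))
            continue
        try:
            rec = next(GOA.gafiterator(io.StringIO(header + line + "\n")))
            ann = GoAnnotation(
                protein_id=rec["DB_Object_ID"],
                go_term=rec["GO_ID"],
                aspect=rec["Aspect"],
                evidence_code=rec["Evidence"],
                negated="NOT" in rec["Qualifier"],
                first_linked_date=_parse_gaf_date(rec["Date"]),
                reference="|".join(rec["DB:Reference"]) or None,
                taxon=_strip_taxon(rec["Taxon_ID"][0]) if rec["Taxon_ID"] else None,
                symbol=rec["DB_Object_Symbol"] or None,
            )
        except (ValueError, KeyError, StopIteration) as exc:
            rejections.append(RejectedRow(lineno, str(exc)))
            continue
        if taxa is not None and ann.taxon not in taxa:
            rejections.append(RejectedRow(lineno, f"taxon {ann.taxon} outside filter"))
            continue
        key = (ann.protein_id, ann.go_term, ann.evidence_code, ann.negated)
        if deduplicate and key in seen:
            rejections.append(RejectedRow(lineno, "duplicate annotation record"))
            continue
        seen.add(key)
        annotations.append(ann)

    if rejections:
        logger.warning(
            "%s: rejected %d of %d data rows (%s%s)",
            path.name,
            len(rejections),
            n_data_rows,
            "; ".join(f"line {r.line_number}: {r.reason}" for r in rejections[:5]),
            "; ..." if len(rejections) > 5 else "",
        )
    return GafReadReport(annotations, rejections, n_data_rows)


def read_gaf(
    path: str | Path,
    taxon_filter: Iterable[str] | None = None,
    deduplicate: bool = True,
) -> list[GoAnnotation]:
    """Read a GAF file, returning the accepted annotations (see
    :func:`read_gaf_report` for rejection accounting)."""
    return read_gaf_report(path, taxon_filter=taxon_filter, deduplicate=deduplicate).annotations


def write_gaf(annotations: Sequence[GoAnnotation], path: str | Path) -> None:
    """Write annotations as a GAF 2.2 file (round-trips with read_gaf)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("!gaf-version: 2.2\n")
        for ann in annotations:
            rec = {
                "DB": "UniProtKB",
                "DB_Object_ID": ann.protein_id,
                "DB_Object_Symbol": ann.symbol or ann.protein_id,
                "Qualifier": ["NOT", "involved_in"] if ann.negated else ["involved_in"],
                "GO_ID": ann.go_term,
                "DB:Reference": (ann.reference or "").split("|"),
                "Evidence": ann.evidence_code,
                "With": [""],
                "Aspect": ann.aspect,
                "DB_Object_Name": "",
                "Synonym": [""],
                "DB_Object_Type": "protein",
                "Taxon_ID": [f"taxon:{ann.taxon}"] if ann.taxon else [""],
                "Date": ann.first_linked_date.strftime("%Y%m%d") if ann.first_linked_date else "",
                "Assigned_By": "unknome",
                "Annotation_Extension": "",
                "Gene_Product_Form_ID": "",
            }
            GOA.writerec(rec, handle, GOA.GAF20FIELDS)


def read_clusters(path: str | Path) -> list[Cluster]:
    """Read a cluster membership TSV (cluster_id, protein_id, taxon, symbol).

    Rows are grouped by cluster id preserving file order of members.  A
    duplicate (cluster, protein) pair raises; the same protein appearing in
    two different clusters is accepted.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False,
        usecols=["cluster_id", "protein_id", "taxon", "symbol"],
    )
    dup = df.duplicated(subset=["cluster_id", "protein_id"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["cluster_id", "protein_id"]].iloc[0]
        raise ValueError(
            f"duplicate member: protein {pair['protein_id']} listed twice in "
            f"cluster {pair['cluster_id']}"
        )
    clusters: list[Cluster] = []
    for cid, grp in df.groupby("cluster_id", sort=False):
        members = tuple(
            (r.protein_id, _strip_taxon(r.taxon), r.symbol) for r in grp.itertuples()
        )
        clusters.append(Cluster(cluster_id=str(cid), members=members))
    return clusters


def write_clusters(clusters: Sequence[Cluster], path: str | Path) -> None:
    rows = [
        {"cluster_id": c.cluster_id, "protein_id": p, "taxon": t, "symbol": s}
        for c in clusters
        for p, t, s in c.members
    ]
    pd.DataFrame(rows, columns=["cluster_id", "protein_id", "taxon", "symbol"]).to_csv(
        path, sep="\t", index=False
    )


def read_weight_scheme(path: str | Path | None = None) -> WeightScheme:
    """Load a weight scheme from a YAML mapping of code -> weight.

    ``None`` returns the default scheme.  Partial configurations are
    completed from the defaults; unknown codes or weights outside [0, 1]
    raise.  An optional ``name`` key names the scheme.
    """
    if path is None:
        return DEFAULT_SCHEME
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise ValueError(f"weight scheme file {path} must be a mapping")
    raw = dict(raw)
    name = str(raw.pop("name", Path(path).stem))
    weights = dict(DEFAULT_WEIGHTS)
    for code, w in raw.items():
        if code not in EVIDENCE_CODES:
            raise ValueError(f"unknown evidence code in weight scheme: {code!r}")
        weights[code] = float(w)
    return WeightScheme(weights=weights, name=name)
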