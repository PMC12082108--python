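"""Genotype-aware splicing analysis: per-clone PSI, dPSI against normal-marrow
controls, event-type classification, and the mutation-bias filters.

All genomic coordinates are 0-based half-open; a junction is keyed by its
intron bounds (chrom, start, end, strand).  PSI is percent spliced-in:
100 x inclusion reads / (inclusion + exclusion reads), reported only when the
event's total supporting coverage in a group reaches ``min_coverage``.

Event conventions
-----------------
* A3SS/A5SS: inclusion = the cryptic (unannotated) junction, exclusion = the
  canonical annotated one; the two share a donor (A3SS) or acceptor (A5SS).
* SE: inclusion = the two exon-flanking junctions, exclusion = the skipping
  junction spanning the annotated internal exon.
* MXE: inclusion/exclusion = the two junction pairs flanking the two
  mutually exclusive exons.
* RI: pure junction counts cannot see retention, so the inclusion signal is
  an intronic-coverage proxy row (kind ``intron_proxy``) in the junction
  table; exclusion is the spliced junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "Junction",
    "junction_id",
    "parse_junction_id",
    "Transcript",
    "GenomeAnnotation",
    "JunctionCountTable",
    "SpliceEvent",
    "PsiTable",
    "pseudobulk_by_genotype",
    "classify_event",
    "compute_psi",
    "psi_table",
    "compute_dpsi",
    "dpsi_table",
    "filter_events",
    "annotate_consequence",
    "events_from_junctions",
]

EVENT_TYPES = ("SE", "A3SS", "A5SS", "RI", "MXE")
CLASSIFICATIONS = ("common", "A-biased", "B-biased", "indeterminate", "null")


class Junction(NamedTuple):
    """A splice junction keyed by its intron bounds (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str
    kind: str = "junction"  # or "intron_proxy" for RI retention evidence


def junction_id(j: Junction) -> str:
    tag = "" if j.kind == "junction" else f":{j.kind}"
    return f"{j.chrom}:{j.start}-{j.end}:{j.strand}{tag}"


def parse_junction_id(jid: str) -> Junction:
    try:
        parts = jid.split(":")
        chrom, span, strand = parts[0], parts[1], parts[2]
        kind = parts[3] if len(parts) > 3 else "junction"
        start, end = span.split("-")
        return Junction(chrom, int(start), int(end), strand, kind)
    except (ValueError, IndexError) as exc:
        raise InputError(f"malformed junction id {jid!r}") from exc


@dataclass(frozen=True)
class Transcript:
    """Exon/CDS structure of one transcript (0-based half-open intervals)."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple
    cds: tuple = ()

    def introns(self) -> tuple:
        ex = sorted(self.exons)
        return tuple((ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1))

    def span(self) -> tuple:
        ex = sorted(self.exons)
        return (ex[0][0], ex[-1][1])

    def cds_span(self):
        if not self.cds:
            return None
        cs = sorted(self.cds)
        return (cs[0][0], cs[-1][1])


class GenomeAnnotation:
    """Lookup structure over a set of transcripts (GTF-lite contents)."""

    def __init__(self, transcripts):
        self.transcripts = {t.transcript_id: t for t in transcripts}
        self._junctions = set()
        self._internal_exons = set()
        for t in self.transcripts.values():
            for s, e in t.introns():
                self._junctions.add((t.chrom, s, e, t.strand))
            ex = sorted(t.exons)
            for s, e in ex[1:-1]:
                self._internal_exons.add((t.chrom, s, e, t.strand))

    def __len__(self):
        return len(self.transcripts)

    def has_junction(self, chrom, start, end, strand) -> bool:
        return (chrom, start, end, strand) in self._junctions

    def has_internal_exon(self, chrom, start, end, strand) -> bool:
        return (chrom, start, end, strand) in self._internal_exons

    def transcripts_overlapping(self, chrom, start, end, strand=None):
        out = []
        for t in self.transcripts.values():
            if t.chrom != chrom or (strand is not None and t.strand != strand):
                continue
            s, e = t.span()
            if s < end and start < e:
                out.append(t)
        return out

    def genes(self):
        by_gene: dict[str, list] = {}
        for t in self.transcripts.values():
            by_gene.setdefault(t.gene_id, []).append(t)
        return by_gene


@dataclass
class JunctionCountTable:
    """Rows = cells or pseudobulk groups; columns = junctions.

    ``genotypes`` labels every row with a clone ({cloneA, cloneB, WT}) or a
    control donor id; ``junctions`` is the BED-like sidecar indexed by
    junction id with columns chrom/start/end/strand/kind.
    """

    counts: pd.DataFrame
    junctions: pd.DataFrame
    genotypes: pd.Series

    def __post_init__(self):
        if self.counts.columns.duplicated().any():
            raise InputError("junction ids must be unique")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("junction counts must be non-negative")
        missing = self.counts.index.difference(self.genotypes.index)
        if len(missing):
            raise InputError(f"rows without a genotype label: {list(missing)[:5]}")
        unknown = self.counts.columns.difference(self.junctions.index)
        if len(unknown):
            raise InputError(f"junction columns absent from sidecar: {list(unknown)[:5]}")

    def junction(self, jid: str) -> Junction:
        row = self.junctions.loc[jid]
        return Junction(row["chrom"], int(row["start"]), int(row["end"]),
                        row["strand"], row.get("kind", "junction"))


@dataclass(frozen=True)
class SpliceEvent:
    """A classified splicing event with inclusion/exclusion junction sets."""

    event_id: str
    gene_id: str
    event_type: str
    inclusion: tuple    # junction ids
    exclusion: tuple    # junction ids
    chrom: str = ""
    strand: str = "+"
    cryptic_offset_nt: int | None = None   # |cryptic - canonical| site distance
    region: tuple | None = None            # genomic segment gained/lost by the event

    def __post_init__(self):
        if set(self.inclusion) & set(self.exclusion):
            raise InputError(f"{self.event_id}: inclusion and exclusion junctions overlap")
        if self.event_type not in EVENT_TYPES + ("unclassified",):
            raise InputError(f"{self.event_id}: unknown event type {self.event_type!r}")


@dataclass
class PsiTable:
    """Per-event, per-group PSI (percent) with total supporting coverage."""

    psi: pd.DataFrame       # events x groups, NaN where coverage < threshold
    coverage: pd.DataFrame  # events x groups, inclusion + exclusion reads
    min_coverage: int


def pseudobulk_by_genotype(table: JunctionCountTable) -> JunctionCountTable:
    """Sum junction counts within each genotype group.

    Control donors keep their own labels, so they stay separate groups.
    """
    if table.genotypes.isna().any():
        bad = table.genotypes.index[table.genotypes.isna()][0]
        raise InputError(f"row {bad!r} has no genotype label")
    labels = table.genotypes.loc[table.counts.index]
    grouped = table.counts.groupby(labels, sort=True).sum()
    grouped.index.name = "group"
    return JunctionCountTable(
        counts=grouped,
        junctions=table.junctions,
        genotypes=pd.Series(grouped.index, index=grouped.index),
    )


def classify_event(inclusion, exclusion, annotation: GenomeAnnotation):
    """Classify an event's junction geometry into SE/A3SS/A5SS/RI/MXE.

    Returns ``(event_type, offset_nt)`` where ``offset_nt`` is the
    cryptic-vs-canonical site distance for A3SS/A5SS, the skipped exon
    length for SE, the intron length for RI, and ``None`` for MXE.
    Geometry matching no type yields ``("unclassified", None)``.
    """
    inc = sorted(inclusion)
    exc = sorted(exclusion)
    if any(j.kind == "intron_proxy" for j in inc):
        if len(inc) == 1 and len(exc) == 1 and (inc[0].start, inc[0].end) == (exc[0].start, exc[0].end):
            return "RI", exc[0].end - exc[0].start
        return "unclassified", None
    if len(inc) == 1 and len(exc) == 1:
        a, b = inc[0], exc[0]
        if a.chrom != b.chrom or a.strand != b.strand:
            return "unclassified", None
        if a.start == b.start and a.end != b.end:
            # shared lower intron bound: the donor on '+', the acceptor on '-'
            return ("A3SS" if a.strand == "+" else "A5SS"), abs(a.end - b.end)
        if a.end == b.end and a.start != b.start:
            return ("A5SS" if a.strand == "+" else "A3SS"), abs(a.start - b.start)
        return "unclassified", None
    if len(inc) == 2 and len(exc) == 1:
        j1, j2 = inc
        skip = exc[0]
        if (skip.start == j1.start and skip.end == j2.end and j1.end < j2.start
                and annotation.has_internal_exon(j1.chrom, j1.end, j2.start, j1.strand)):
            return "SE", j2.start - j1.end
        return "unclassified", None
    if len(inc) == 2 and len(exc) == 2:
        i1, i2 = inc
        e1, e2 = exc
        exon_i = (i1.end, i2.start)
        exon_e = (e1.end, e2.start)
        if (i1.start == e1.start and i2.end == e2.end
                and exon_i != exon_e
                and (exon_i[1] <= exon_e[0] or exon_e[1] <= exon_i[0])
                and annotation.has_internal_exon(i1.chrom, *exon_i, i1.strand)
                and annotation.has_internal_exon(e1.chrom, *exon_e, e1.strand)):
            return "MXE", None
        return "unclassified", None
    return "unclassified", None


def compute_psi(event: SpliceEvent, counts, min_coverage: int = 10):
    """PSI (percent) of one event in one row of counts; NaN below coverage.

    ``counts`` is a mapping/Series of junction id -> reads; junctions absent
    from it count as zero.
    """
    inc = sum(int(counts.get(j, 0)) for j in event.inclusion)
    exc = sum(int(counts.get(j, 0)) for j in event.exclusion)
    total = inc + exc
    if total < min_coverage:
        return float("nan")
    return 100.0 * inc / total


def psi_table(events, table: JunctionCountTable, min_coverage: int = 10) -> PsiTable:
    """PSI for every event in every row (cell or pseudobulk group)."""
    groups = list(table.counts.index)
    psi = pd.DataFrame(index=[e.event_id for e in events], columns=groups, dtype=float)
    cov = pd.DataFrame(0, index=psi.index, columns=groups, dtype=int)
    for e in events:
        inc_cols = [j for j in e.inclusion if j in table.counts.columns]
        exc_cols = [j for j in e.exclusion if j in table.counts.columns]
        inc = table.counts[inc_cols].sum(axis=1) if inc_cols else pd.Series(0, index=groups)
        exc = table.counts[exc_cols].sum(axis=1) if exc_cols else pd.Series(0, index=groups)
        total = inc + exc
        cov.loc[e.event_id] = total
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = 100.0 * inc / total
        vals[total < min_coverage] = np.nan
        psi.loc[e.event_id] = vals
    psi.index.name = cov.index.name = "event_id"
    return PsiTable(psi=psi, coverage=cov, min_coverage=min_coverage)


def compute_dpsi(psi_clone: float, psi_controls) -> float:
    """dPSI = clone PSI minus the unweighted mean of per-donor control PSIs.

    Missing control donors are dropped; if the clone PSI or every control is
    missing, the dPSI is missing.
    """
    controls = np.asarray([p for p in psi_controls if not np.isnan(p)], dtype=float)
    if np.isnan(psi_clone) or controls.size == 0:
        return float("nan")
    return float(psi_clone - controls.mean())


def dpsi_table(
    psis: PsiTable,
    clone_groups=("cloneA", "cloneB"),
    control_groups=None,
) -> pd.DataFrame:
    """Per-event dPSI of each mutant clone against the control-donor mean.

    ``control_groups`` defaults to every group not named in ``clone_groups``
    (and not WT).  Returns a DataFrame indexed by event id with columns
    ``dpsi_cloneA``/``dpsi_cloneB`` (named after the clone groups).
    """
    groups = list(psis.psi.columns)
    if control_groups is None:
        control_groups = [g for g in groups if g not in clone_groups and g != "WT"]
    missing = [g for g in tuple(clone_groups) + tuple(control_groups) if g not in groups]
    if missing:
        raise InputError(f"groups absent from PSI table: {missing}")
    if not control_groups:
        raise InputError("no control groups available for dPSI")
    out = pd.DataFrame(index=psis.psi.index)
    ctrl = psis.psi[list(control_groups)]
    for g in clone_groups:
        out[f"dpsi_{g}"] = [
            compute_dpsi(psis.psi.at[ev, g], ctrl.loc[ev].to_numpy())
            for ev in psis.psi.index
        ]
    return out


def _classify_record(d_a, d_b, common_threshold, bias_threshold, require_sign_concordance):
    if np.isnan(d_a) or np.isnan(d_b):
        return "indeterminate"
    aa, ab = abs(d_a), abs(d_b)
    if aa > common_threshold and ab > common_threshold:
        if require_sign_concordance and np.sign(d_a) != np.sign(d_b):
            return "indeterminate"
        return "common"
    if aa > common_threshold and ab < bias_threshold:
        return "A-biased"
    if ab > common_threshold and aa < bias_threshold:
        return "B-biased"
    if aa < common_threshold and ab < common_threshold:
        return "null"
    return "indeterminate"


def filter_events(
    records: pd.DataFrame,
    common_threshold: float = 2.0,
    bias_threshold: float = 2.0,
    require_sign_concordance: bool = True,
    clone_columns=("dpsi_cloneA", "dpsi_cloneB"),
    diagonal_band: float = 10.0,
) -> pd.DataFrame:
    """Apply the common / mutation-biased dPSI filters.

    An event is *common* when both clones shift against control by more
    than ``common_threshold`` percent (same direction unless sign
    concordance is disabled); *X-biased* when clone X shifts by more than
    ``common_threshold`` while the other clone's |dPSI| stays below
    ``bias_threshold``; values exactly on a threshold are *indeterminate*;
    both below threshold is *null*.  Also reports the clone-clone dPSI and
    whether it sits inside the |difference| < ``diagonal_band`` band.
    """
    col_a, col_b = clone_columns
    out = records.copy()
    out["clone_clone_dpsi"] = out[col_a] - out[col_b]
    out["classification"] = [
        _classify_record(a, b, common_threshold, bias_threshold, require_sign_concordance)
        for a, b in zip(out[col_a], out[col_b])
    ]
    out["within_diagonal_band"] = out["clone_clone_dpsi"].abs() < diagonal_band
    return out


def annotate_consequence(event: SpliceEvent, annotation: GenomeAnnotation) -> str:
    """Predicted coding consequence of an event's gained/lost segment.

    If the segment lies within an overlapping transcript's CDS span, the
    frame offset decides: offset % 3 == 0 -> ``in-frame``, else
    ``frameshift``; a segment confined to UTR or a non-coding transcript is
    ``noncoding``; no overlapping transcript at all -> ``unannotated``.
    """
    region = event.region
    if region is None:
        raise InputError(f"{event.event_id}: no genomic region recorded for the event")
    start, end = region
    hits = annotation.transcripts_overlapping(event.chrom, start, end, event.strand)
    if not hits:
        return "unannotated"
    offset = event.cryptic_offset_nt if event.cryptic_offset_nt is not None else end - start
    for t in hits:
        span = t.cds_span()
        if span and start < span[1] and span[0] < end:
            return "in-frame" if offset % 3 == 0 else "frameshift"
    return "noncoding"


def _event_region(etype, inc, exc):
    """Genomic segment distinguishing the two isoforms of an event."""
    if etype in ("A3SS", "A5SS"):
        a, b = inc[0], exc[0]
        if a.start == b.start:
            lo, hi = sorted((a.end, b.end))
        else:
            lo, hi = sorted((a.start, b.start))
        return (lo, hi)
    if etype == "SE":
        return (inc[0].end, inc[1].start)
    if etype == "RI":
        return (exc[0].start, exc[0].end)
    if etype == "MXE":
        return (inc[0].end, inc[1].start)
    return None


def events_from_junctions(table: JunctionCountTable, annotation: GenomeAnnotation):
    """Reconstruct splicing events from a junction table and annotation.

    Junctions are assigned to genes by overlap; within each gene, cryptic
    (unannotated) junctions are matched against canonical annotated ones to
    form A3SS/A5SS/SE events, intron proxies form RI events, and annotated
    junction pairs flanking mutually exclusive internal exons form MXE
    events.  Junctions matching no geometry are ignored.
    """
    juncs = [table.junction(jid) for jid in table.counts.columns]
    by_gene: dict[str, list] = {}
    for j in juncs:
        hits = annotation.transcripts_overlapping(j.chrom, j.start, j.end, j.strand)
        genes = sorted({t.gene_id for t in hits})
        if genes:
            by_gene.setdefault(genes[0], []).append(j)

    events = []

    def add(gene, etype, inc, exc, offset):
        region = _event_region(etype, sorted(inc), sorted(exc))
        events.append(SpliceEvent(
            event_id=f"{gene}.{etype}{sum(1 for e in events if e.gene_id == gene) + 1}",
            gene_id=gene,
            event_type=etype,
            inclusion=tuple(junction_id(j) for j in sorted(inc)),
            exclusion=tuple(junction_id(j) for j in sorted(exc)),
            chrom=inc[0].chrom,
            strand=inc[0].strand,
            cryptic_offset_nt=offset,
            region=region,
        ))

    for gene in sorted(by_gene):
        gjuncs = by_gene[gene]
        proxies = [j for j in gjuncs if j.kind == "intron_proxy"]
        real = [j for j in gjuncs if j.kind == "junction"]
        annotated = [j for j in real if annotation.has_junction(*j[:4])]
        cryptic = [j for j in real if not annotation.has_junction(*j[:4])]

        for p in proxies:
            for a in annotated:
                etype, off = classify_event([p], [a], annotation)
                if etype == "RI":
                    add(gene, "RI", [p], [a], off)
                    break

        used = set()
        for c in cryptic:
            if c in used:
                continue
            # exon skipping first: a skip junction also shares a bound with
            # each flanking junction and must not fall through to alt-site
            flank = [(a1, a2) for a1 in annotated for a2 in annotated
                     if a1.start == c.start and a2.end == c.end and a1.end < a2.start]
            se_done = False
            for a1, a2 in flank:
                etype, off = classify_event([a1, a2], [c], annotation)
                if etype == "SE":
                    add(gene, "SE", [a1, a2], [c], off)
                    used.add(c)
                    se_done = True
                    break
            if se_done:
                continue
            # alternative splice site: cryptic junction sharing one bound
            partner = next(
                (a for a in annotated if (a.start == c.start) != (a.end == c.end)), None
            )
            if partner is not None:
                etype, off = classify_event([c], [partner], annotation)
                if etype in ("A3SS", "A5SS"):
                    add(gene, etype, [c], [partner], off)
                    used.add(c)

        # mutually exclusive exons among annotated junctions
        seen_pairs = set()
        for i1 in annotated:
            for i2 in annotated:
                if i1.end >= i2.start:
                    continue
                for e1 in annotated:
                    for e2 in annotated:
                        if (e1, e2) in ((i1, i2),) or e1.end >= e2.start:
                            continue
                        key = frozenset([(i1, i2), (e1, e2)])
                        if key in seen_pairs:
                            continue
                        etype, off = classify_event([i1, i2], [e1, e2], annotation)
                        if etype == "MXE" and (i1.end, i2.start) < (e1.end, e2.start):
                            seen_pairs.add(key)
                            add(gene, "MXE", [i1, i2], [e1, e2], off)
    return events
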