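"""Feature-containment evaluation of an assembly.

A desk-scale analogue of validating an assembly against independently
derived reference features (cloned genomic fragments, core genes): each
nucleotide feature is aligned to the assembly by 15-mer seeding and
chaining, its coverage and identity on the best *single* target are
recorded, and the summary reports what fraction of features have at
least 90% of their length contained in one contig and in one scaffold.
N-runs in scaffolds never seed matches and are subtracted from covered
spans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .chaining import KmerIndex, collect_hits, extract_chains
from .util import revcomp

log = logging.getLogger(__name__)


@dataclass
class FeatureRecord:
    feature_id: str
    target_id: str | None
    covered_fraction: float
    identity: float

    @property
    def contained_90(self) -> bool:
        return self.covered_fraction >= 0.9


@dataclass
class ContainmentReport:
    contig_records: list[FeatureRecord]
    scaffold_records: list[FeatureRecord]
    summary: dict = field(default_factory=dict)


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
    return total


def align_feature(
    feature_id: str,
    feature_seq: str,
    targets,
    index: KmerIndex | None = None,
    min_seed: int = 15,
    tolerance: float = 0.2,
) -> FeatureRecord:
    """Best single-target alignment of one feature.

    15-mer chains of the feature against each target are collected (both
    strands, several loci per target allowed so a feature spanning a
    scaffold gap still accrues to that one scaffold); the target with the
    most covered feature bases wins, ties broken by identity then smaller
    id.  Covered spans exclude N bases of the target; identity is the
    edit-distance identity of the chained segments.
    """
    if len(feature_seq) < min_seed:
        raise ValueError("feature shorter than the seed size")
    seqs = _as_dict(targets)
    if index is None:
        index = KmerIndex(seqs)
    groups = collect_hits(feature_seq, index)
    per_target: dict[str, list] = {}
    for (tid, rel), hits in sorted(groups.items()):
        for chain in extract_chains(hits, tolerance, min_hits=1,
                                    max_loci=8):
            per_target.setdefault(tid, []).append((chain, rel))
    best = None  # (covered, identity, tid)
    for tid in sorted(per_target):
        covered_ivals = []
        ident_num = 0.0
        ident_den = 0
        for chain, rel in per_target[tid]:
            q0, q1 = chain.query_interval
            t0, t1 = chain.target_interval
            tseq = seqs[tid] if rel == "+" else revcomp(seqs[tid])
            n_count = tseq[t0:t1].count("N")
            covered_ivals.append((q0, max(q0, q1 - n_count)))
            dist = edlib.align(feature_seq[q0:q1], tseq[t0:t1],
                               task="distance")["editDistance"]
            seg = q1 - q0
            ident_num += max(0.0, 1.0 - dist / max(seg, 1)) * seg
            ident_den += seg
        covered = _union_length(covered_ivals)
        identity = ident_num / ident_den if ident_den else 0.0
        cand = (covered / len(feature_seq), identity, tid)
        if best is None or (cand[0], cand[1], _neg_id(cand[2])) > (
            best[0], best[1], _neg_id(best[2])
        ):
            best = cand
    if best is None:
        return FeatureRecord(feature_id=feature_id, target_id=None,
                             covered_fraction=0.0, identity=0.0)
    return FeatureRecord(
        feature_id=feature_id, target_id=best[2],
        covered_fraction=min(1.0, best[0]), identity=min(1.0, best[1]),
    )


class _neg_id(str):
    """Inverts string comparison so max() prefers the smaller target id."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _as_dict(targets) -> dict[str, str]:
    if isinstance(targets, dict):
        return dict(targets)
    out = {}
    for t in targets:
        if isinstance(t, tuple):
            out[t[0]] = t[1]
        else:  # Contig / Scaffold objects
            out[t.id] = t.sequence
    return out


def containment_summary(
    features, contigs, scaffolds=None
) -> ContainmentReport:
    """Aggregate per-feature alignments at contig and scaffold level.

    ``features`` is a mapping or list of (id, sequence).  The summary
    reports the percent of features with any alignment, the mean identity
    over aligned features, and the percent contained >= 90% in a single
    contig and in a single scaffold.
    """
    feats = list(_as_dict(features).items())
    if not feats:
        raise ValueError("feature set is empty")
    contig_seqs = _as_dict(contigs)
    contig_index = KmerIndex(contig_seqs)
    contig_records = [
        align_feature(fid, fseq, contig_seqs, index=contig_index)
        for fid, fseq in feats
    ]
    scaffold_records = []
    if scaffolds is not None:
        scaffold_seqs = _as_dict(scaffolds)
        scaffold_index = KmerIndex(scaffold_seqs)
        scaffold_records = [
            align_feature(fid, fseq, scaffold_seqs, index=scaffold_index)
            for fid, fseq in feats
        ]
    aligned = [r for r in contig_records if r.covered_fraction > 0]
    n = len(feats)
    summary = {
        "n_features": n,
        "pct_features_covered": 100.0 * len(aligned) / n,
        "mean_identity": (
            sum(r.identity for r in aligned) / len(aligned) if aligned
            else 0.0
        ),
        "pct_contained_90_contig": 100.0 * sum(
            r.contained_90 for r in contig_records
        ) / n,
        "pct_contained_90_scaffold": 100.0 * sum(
            r.contained_90 for r in scaffold_records
        ) / n if scaffold_records else None,
    }
    return ContainmentReport(
        contig_records=contig_records,
        scaffold_records=scaffold_records,
        summary=summary,
    )


def write_report(report: ContainmentReport, tsv_path, json_path=None):
    import json

    with open(tsv_path, "w") as fh:
        fh.write("feature_id\tlevel\ttarget_id\tcovered_fraction\t"
                 "identity\tcontained_90\n")
        for level, records in (("contig", report.contig_records),
                               ("scaffold", report.scaffold_records)):
            for r in records:
                fh.write(
                    f"{r.feature_id}\t{level}\t{r.target_id or '.'}\t"
                    f"{r.covered_fraction:.4f}\t{r.identity:.4f}\t"
                    f"{int(r.contained_90)}\n"
                )
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(report.summary, fh, indent=2)
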