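"""Read classification against marker-gene k-mer indexes and abundance tallies.

Reads are assigned by exact canonical k-mer matching to flat gene-set labels
(e.g. the HK97-fold MCP genes of tailed phages vs the DJR MCP genes of
tailless varidnaviruses, subdivided by group); ties and zero-hit reads stay
unclassified. Derived statistics (fold ratios, dataset prevalence, within-set
percentages) are exact rationals with display rounding on top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import pandas as pd

from .core_model import Read

_COMP = str.maketrans("ACGT", "TGCA")


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_COMP)[::-1]
    return kmer if kmer <= rc else rc


@dataclass
class KmerIndex:
    k: int
    kmers: dict  # canonical k-mer -> label
    labels: list
    n_conflicts: int = 0  # cross-label k-mers removed during the build

    def lookup(self, kmer: str) -> Optional[str]:
        return self.kmers.get(_canonical(kmer))


def build_index(gene_sets: dict, k: int = 31) -> KmerIndex:
    """Index all canonical k-mers of each labeled gene set.

    K-mers shared between labels are dropped (and counted); sequences shorter
    than k are skipped with a warning entry in the conflict count's favor.
    """
    kmers: dict[str, str] = {}
    conflicted: set[str] = set()
    for label in sorted(gene_sets):
        for seq in gene_sets[label]:
            seq = seq.upper()
            if len(seq) < k:
                continue
            for i in range(len(seq) - k + 1):
                km = _canonical(seq[i : i + k])
                if "N" in km:
                    continue
                prev = kmers.get(km)
                if prev is None:
                    kmers[km] = label
                elif prev != label:
                    conflicted.add(km)
    for km in conflicted:
        del kmers[km]
    return KmerIndex(k, kmers, sorted(gene_sets), len(conflicted))


@dataclass
class AbundanceReport:
    """Per-dataset and global classified-read counts."""

    counts: pd.DataFrame  # datasets x (labels + 'unclassified'), int
    k: int

    @property
    def labels(self) -> list:
        return [c for c in self.counts.columns if c != "unclassified"]

    def total_reads(self, dataset: Optional[str] = None) -> int:
        if dataset is None:
            return int(self.counts.to_numpy().sum())
        return int(self.counts.loc[dataset].sum())

    def label_total(self, label: str) -> int:
        return int(self.counts[label].sum()) if label in self.counts else 0


def classify_reads(reads: Sequence[Read], index: KmerIndex) -> AbundanceReport:
    """Assign each read to the label with the most matching k-mers.

    Zero matching k-mers, or a tie between top labels, leaves the read
    unclassified. Counts are tallied per dataset id.
    """
    tallies: dict[str, dict[str, int]] = {}
    cols = index.labels + ["unclassified"]
    for r in reads:
        votes: dict[str, int] = {}
        seq = r.seq.upper()
        for i in range(len(seq) - index.k + 1):
            label = index.lookup(seq[i : i + index.k])
            if label is not None:
                votes[label] = votes.get(label, 0) + 1
        if votes:
            best = max(votes.values())
            winners = [lab for lab, v in votes.items() if v == best]
            assigned = winners[0] if len(winners) == 1 else "unclassified"
        else:
            assigned = "unclassified"
        ds = tallies.setdefault(r.dataset_id or "default", {c: 0 for c in cols})
        ds[assigned] += 1
    if not tallies:
        counts = pd.DataFrame(columns=cols, dtype=int)
    else:
        counts = pd.DataFrame.from_dict(tallies, orient="index")[cols].astype(int)
        counts = counts.sort_index()
    return AbundanceReport(counts, index.k)


# --------------------------------------------------------------------- summaries


def round_fold(x: float) -> float:
    """Display rounding for fold ratios: nearest hundred when >= 1000."""
    return round(x / 100) * 100 if x >= 1000 else round(x, 1)


def summarize_counts(
    label_totals: dict,
    datasets_with_label: Optional[dict] = None,
    n_datasets: Optional[int] = None,
    numerator: str = "HK97",
    denominator_prefix: str = "DJR",
) -> dict:
    """Derived statistics from a label -> total-read-count table.

    Computes the fold ratio of ``numerator`` reads over the summed
    ``denominator_prefix:*`` (or plain ``denominator_prefix``) reads, per-label
    dataset prevalence and within-denominator percentages. All ratios are kept
    as exact :class:`fractions.Fraction` plus rounded display values; a zero
    denominator yields ``None`` ("undefined"), never infinity.
    """
    denom_labels = [
        lab
        for lab in label_totals
        if lab == denominator_prefix or lab.startswith(denominator_prefix + ":")
    ]
    denom_total = sum(label_totals[lab] for lab in denom_labels)
    num_total = label_totals.get(numerator, 0)
    out: dict = {
        "totals": dict(label_totals),
        "denominator_total": denom_total,
        "fold_ratio": None,
        "fold_ratio_display": None,
        "within_percent": {},
        "dataset_prevalence": {},
    }
    if denom_total > 0:
        ratio = Fraction(num_total, denom_total)
        out["fold_ratio"] = ratio
        out["fold_ratio_display"] = round_fold(float(ratio))
        for lab in denom_labels:
            frac = Fraction(label_totals[lab], denom_total)
            out["within_percent"][lab] = {
                "fraction": frac,
                "percent": 100.0 * float(frac),
                "display": round(100 * float(frac)),
            }
    if datasets_with_label and n_datasets:
        for lab, nd in datasets_with_label.items():
            frac = Fraction(nd, n_datasets)
            out["dataset_prevalence"][lab] = {
                "fraction": frac,
                "percent": 100.0 * float(frac),
                "display": round(100 * float(frac)),
            }
    return out


def summarize(report: AbundanceReport, **kw) -> dict:
    """Derived statistics recomputed purely from the report's count table."""
    if report.counts.empty:
        raise ValueError("empty abundance report")
    totals = {lab: report.label_total(lab) for lab in report.labels}
    datasets_with = {
        lab: int((report.counts[lab] > 0).sum()) for lab in report.labels
    }
    return summarize_counts(
        totals, datasets_with_label=datasets_with, n_datasets=len(report.counts), **kw
    )


def save_index(index: KmerIndex, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "k": index.k,
                "labels": index.labels,
                "n_conflicts": index.n_conflicts,
                "kmers": index.kmers,
            },
            fh,
        )


def load_index(path) -> KmerIndex:
    with open(path) as fh:
        obj = json.load(fh)
    return KmerIndex(obj["k"], obj["kmers"], obj["labels"], obj["n_conflicts"])
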