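"""Indexed-amplicon read processing: demultiplexing, matching, allele counts.

Reads are single-end: a 5-base sample index followed by an amplicon insert in
either orientation.  Index 5-mers carry a built-in redundancy — the 1st and
5th bases are identical — which allows an optional single-mismatch correction
mode.  Each read is assigned to its sample by index, to its (gene,
orientation) by ungapped identity against a reference library of amplicons
and their reverse complements, and its mSNP base is accepted only when the
20-bp flanks on both sides of the mSNP verify against the amplicon.  Reads
failing any stage are triaged (failed match / missing mSNP base) and the
survivors are tabulated into per-(sample, gene, template) allele counts.

Coordinates are 0-based throughout.  Base qualities are parsed but not used
for filtering; the only length gate is a minimum read length (default 30).
"""

from __future__ import annotations

import json
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SampleIndex",
    "AmpliconReference",
    "ReferenceLibrary",
    "TriageReport",
    "CountResult",
    "Demultiplexer",
    "parse_fastq",
    "demultiplex",
    "match_read",
    "extract_allele",
    "count_reads",
    "tabulate_counts",
    "revcomp",
    "load_reference",
    "write_reference",
    "load_index_map",
    "write_index_map",
    "load_genotypes",
    "write_genotypes",
    "read_counts",
    "write_counts",
]

INDEX_LENGTH = 5
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC codes and the bases they cover (for reference-sequence validation)
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SampleIndex:
    """A 5-base sample index with 1st-base == 5th-base redundancy."""

    sample_id: str
    index_seq: str

    def __post_init__(self) -> None:
        s = self.index_seq
        if len(s) != INDEX_LENGTH:
            raise ValueError(f"index {s!r} must be exactly {INDEX_LENGTH} bases")
        if set(s) - set("ACGT"):
            raise ValueError(f"index {s!r} contains non-ACGT characters")
        if s[0] != s[4]:
            raise ValueError(
                f"index {s!r} violates the redundancy rule (base 1 must equal base 5)"
            )


@dataclass(frozen=True)
class AmpliconReference:
    """One candidate gene's amplicon with its marker SNP.

    ``msnp_offset`` is the 0-based position of the mSNP within
    ``amplicon_seq``; ``numerator_allele`` names which mSNP allele (M or m)
    forms the AEI ratio's numerator for this gene.
    """

    gene: str
    amplicon_seq: str
    msnp_offset: int
    allele_M: str
    allele_m: str
    numerator_allele: str

    def __post_init__(self) -> None:
        n = len(self.amplicon_seq)
        if not (66 <= n <= 100):
            raise ValueError(f"{self.gene}: amplicon length {n} outside 66..100")
        if not (0 <= self.msnp_offset < n):
            raise ValueError(f"{self.gene}: msnp_offset {self.msnp_offset} out of range")
        if self.allele_M == self.allele_m:
            raise ValueError(f"{self.gene}: M and m alleles must differ")
        for a in (self.allele_M, self.allele_m):
            if a not in "ACGT" or len(a) != 1:
                raise ValueError(f"{self.gene}: allele {a!r} must be a single ACGT base")
        if self.numerator_allele not in ("M", "m"):
            raise ValueError(f"{self.gene}: numerator_allele must be 'M' or 'm'")
        site = self.amplicon_seq[self.msnp_offset].upper()
        covered = _IUPAC.get(site, "")
        if not (self.allele_M in covered or self.allele_m in covered):
            raise ValueError(
                f"{self.gene}: reference base {site!r} at the mSNP covers neither allele"
            )


class Demultiplexer:
    """Assign reads to samples by their 5-base index prefix.

    mode="exact": only perfect 5-mer matches are assigned.  mode="correct":
    a unique index matching at >= 4 of 5 positions is also accepted, provided
    the read is consistent with the 1st==5th redundancy — a mismatch at an
    interior position (2-4) requires the read's own 1st and 5th bases to
    agree, while a mismatch at position 1 or 5 is the redundancy doing its
    job.  Ties are never resolved arbitrarily: they yield no assignment.
    """

    def __init__(self, indices, mode: str = "exact"):
        if mode not in ("exact", "correct"):
            raise ValueError("mode must be 'exact' or 'correct'")
        self.indices = list(indices)
        self.mode = mode
        seqs = [i.index_seq for i in self.indices]
        if len(set(seqs)) != len(seqs):
            dup = [s for s, c in Counter(seqs).items() if c > 1]
            raise ValueError(f"duplicate index sequences in run: {dup}")
        self._exact = {i.index_seq: i.sample_id for i in self.indices}

    def assign(self, read_sequence: str) -> str | None:
        prefix = read_sequence[:INDEX_LENGTH]
        if len(prefix) < INDEX_LENGTH:
            return None
        hit = self._exact.get(prefix)
        if hit is not None or self.mode == "exact":
            return hit
        best: list[tuple[int, SampleIndex]] = []
        best_mm = INDEX_LENGTH + 1
        for idx in self.indices:
            mm = [p for p in range(INDEX_LENGTH) if prefix[p] != idx.index_seq[p]]
            if len(mm) < best_mm:
                best_mm = len(mm)
                best = [(mm[0], idx)] if mm else []
            elif len(mm) == best_mm and mm:
                best.append((mm[0], idx))
        if best_mm != 1 or len(best) != 1:
            return None  # too many errors, or a tie
        mm_pos, idx = best[0]
        if mm_pos not in (0, 4) and prefix[0] != prefix[4]:
            return None  # interior mismatch but broken redundancy: untrusted
        return idx.sample_id


def demultiplex(read_sequence: str, indices, mode: str = "exact") -> str | None:
    """One-shot convenience wrapper over :class:`Demultiplexer`."""
    return Demultiplexer(indices, mode=mode).assign(read_sequence)


class ReferenceLibrary:
    """Amplicons and their reverse complements for ungapped identity matching.

    Replaces an external aligner: amplicons are short (66-100 bp) and
    indels are not modeled, so the top hit under ungapped identity over the
    aligned overlap is well defined and oracle-testable.  The full indexed
    library cardinality is n_indices x n_genes x 2 (see ``cardinality``);
    matching operates on the read after the index, so only n_genes x 2
    sequences are stored.
    """

    def __init__(self, entries: list[tuple[str, str, str]]):
        # entries: (gene, orientation, sequence)
        self.entries = entries
        self._arrays = [
            (g, o, np.frombuffer(s.encode(), dtype=np.uint8)) for g, o, s in entries
        ]

    @classmethod
    def from_references(cls, references) -> "ReferenceLibrary":
        entries = []
        for r in references:
            entries.append((r.gene, "forward", r.amplicon_seq))
            entries.append((r.gene, "reverse", revcomp(r.amplicon_seq)))
        return cls(entries)

    def __len__(self) -> int:
        return len(self.entries)

    @staticmethod
    def cardinality(n_indices: int, n_genes: int) -> int:
        """Size of the fully expanded index x gene x orientation library."""
        return n_indices * n_genes * 2

    def match(
        self, seq: str, min_identity: float = 0.9, min_length: int = 25
    ) -> tuple[str, str] | None:
        """Best (gene, orientation) by ungapped identity, or None.

        Identity is computed over the aligned overlap from position 0.  Reads
        shorter than ``min_length`` never match; a best-identity tie across
        distinct genes is ambiguous and returns None (within one gene the
        forward orientation is preferred deterministically).
        """
        if len(seq) < min_length or not self.entries:
            return None
        s = np.frombuffer(seq.encode(), dtype=np.uint8)
        best_ident = -1.0
        hits: list[tuple[str, str]] = []
        for gene, orient, ref in self._arrays:
            L = min(s.size, ref.size)
            ident = float(np.count_nonzero(s[:L] == ref[:L])) / L
            if ident > best_ident + 1e-12:
                best_ident = ident
                hits = [(gene, orient)]
            elif abs(ident - best_ident) <= 1e-12:
                hits.append((gene, orient))
        if best_ident < min_identity:
            return None
        genes = {g for g, _ in hits}
        if len(genes) > 1:
            return None
        gene = hits[0][0]
        orients = [o for _, o in hits]
        return (gene, "forward" if "forward" in orients else orients[0])


def match_read(seq, library: ReferenceLibrary, min_identity: float = 0.9,
               min_length: int = 25):
    """Functional wrapper over :meth:`ReferenceLibrary.match`."""
    return library.match(seq, min_identity=min_identity, min_length=min_length)


def extract_allele(
    read_seq: str,
    reference: AmpliconReference,
    orientation: str,
    flank_len: int = 20,
    max_flank_mismatch: int = 2,
) -> str:
    """mSNP allele carried by a matched read: 'M', 'm', 'neither' or 'missing'.

    The read (already stripped of its index) is orientation-normalized onto
    amplicon coordinates; reverse reads align to the amplicon's 3' end.  The
    base at the mSNP is reported as M or m only when the up- and downstream
    flanks (up to ``flank_len`` bases each, truncated at read/amplicon ends)
    each show at most ``max_flank_mismatch`` mismatches; an uncovered mSNP is
    'missing', and a covered base equal to neither allele — or unverifiable
    flanks — is 'neither'.
    """
    amp = reference.amplicon_seq
    if orientation == "forward":
        s = read_seq
    elif orientation == "reverse":
        s = revcomp(read_seq)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    # Reads begin at one amplicon end, so the normalized sequence is anchored
    # either at the amplicon start (a forward read, or the reverse complement
    # of a reverse read) or at its end (the converse).  Score both anchors and
    # keep the better alignment; this makes extraction invariant under
    # reverse-complementing the read with flipped orientation.
    candidates = []
    for anchor in ("start", "end"):
        si = s
        shift = 0 if anchor == "start" else len(amp) - len(si)
        if shift < 0:  # read longer than the amplicon: clip the overhang
            si = si[: len(amp)] if anchor == "start" else si[-shift:]
            shift = 0
        overlap = min(len(si), len(amp) - shift)
        matches = sum(
            1 for i in range(overlap) if si[i].upper() == amp[shift + i].upper()
        )
        candidates.append((matches, anchor == "start", si, shift))
    _, _, s, shift = max(candidates)
    end = min(shift + len(s), len(amp))
    off = reference.msnp_offset
    if not (shift <= off < end):
        return "missing"
    base = s[off - shift].upper()
    up_start = max(shift, off - flank_len)
    up_mm = sum(
        1 for i in range(up_start, off) if s[i - shift].upper() != amp[i].upper()
    )
    down_end = min(end, off + 1 + flank_len)
    down_mm = sum(
        1 for i in range(off + 1, down_end) if s[i - shift].upper() != amp[i].upper()
    )
    if up_mm > max_flank_mismatch or down_mm > max_flank_mismatch:
        return "neither"
    if base == reference.allele_M.upper():
        return "M"
    if base == reference.allele_m.upper():
        return "m"
    return "neither"


@dataclass
class TriageReport:
    """Read-level quality-control accounting.

    total = failed_match + missing_msnp_base + usable; ``single_allele_only``
    counts usable reads belonging to (sample, gene) pairs where a recorded
    heterozygote yielded only one allele (a genotype-discordance signal) — a
    flagged subset of usable, not a separate triage class.
    """

    total_reads: int = 0
    failed_match: int = 0
    missing_msnp_base: int = 0
    single_allele_only: int = 0
    usable: int = 0
    read_length_histogram: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.total_reads != self.failed_match + self.missing_msnp_base + self.usable:
            raise ValueError("triage counts do not conserve total reads")
        if min(self.total_reads, self.failed_match, self.missing_msnp_base,
               self.usable, self.single_allele_only) < 0:
            raise ValueError("triage counts must be non-negative")

    def fractions(self) -> dict:
        t = max(self.total_reads, 1)
        return {
            "failed_match": self.failed_match / t,
            "missing_msnp_base": self.missing_msnp_base / t,
            "usable": self.usable / t,
            "single_allele_only": self.single_allele_only / t,
        }

    def to_json(self, path) -> None:
        self.validate()
        with open(path, "w") as fh:
            json.dump(
                {
                    "total_reads": self.total_reads,
                    "failed_match": self.failed_match,
                    "missing_msnp_base": self.missing_msnp_base,
                    "single_allele_only": self.single_allele_only,
                    "usable": self.usable,
                    "fractions": self.fractions(),
                    "read_length_histogram": {
                        str(k): v for k, v in sorted(self.read_length_histogram.items())
                    },
                },
                fh,
                indent=1,
            )


@dataclass
class CountResult:
    counts: pd.DataFrame
    triage: TriageReport
    exclusions: list[dict]


def parse_fastq(path):
    """Stream (read_id, sequence, quality) records from a FASTQ file.

    Sanger/Phred+33 four-line records; a malformed record raises a ValueError
    naming the approximate line number.
    """
    n = 0
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as e:
                raise ValueError(
                    f"malformed FASTQ record near line {4 * n + 1} of {path}: {e}"
                ) from e
            n += 1
            yield title.split()[0], seq, qual


def count_reads(
    reads,
    indices,
    references,
    template: str,
    genotypes: pd.DataFrame | None = None,
    *,
    index_mode: str = "exact",
    min_identity: float = 0.9,
    min_read_length: int = 30,
    flank_len: int = 20,
    max_flank_mismatch: int = 2,
) -> CountResult:
    """Full read triage and allele tabulation for one template.

    ``reads`` is an iterable of (read_id, sequence, quality) — typically
    :func:`parse_fastq` output.  ``genotypes`` (sample_id, gene, genotype in
    {MM, Mm, mm}) restricts records to heterozygous samples: counts for
    samples missing from the table or homozygous at the mSNP are excluded
    with a reason, and heterozygous records showing a single allele are
    flagged.  Returns counts, a TriageReport and the exclusion list.
    """
    if template not in ("gDNA", "cDNA"):
        raise ValueError("template must be 'gDNA' or 'cDNA'")
    demux = Demultiplexer(indices, mode=index_mode)
    refs = list(references)
    library = ReferenceLibrary.from_references(refs)
    ref_by_gene = {r.gene: r for r in refs}
    triage = TriageReport()
    hist: Counter = Counter()
    counts: dict[tuple[str, str], dict[str, int]] = defaultdict(
        lambda: {"M": 0, "m": 0}
    )
    for _read_id, seq, _qual in reads:
        triage.total_reads += 1
        hist[len(seq)] += 1
        if len(seq) < min_read_length:
            triage.failed_match += 1
            continue
        sample = demux.assign(seq)
        if sample is None:
            triage.failed_match += 1
            continue
        body = seq[INDEX_LENGTH:]
        hit = library.match(body, min_identity=min_identity,
                            min_length=max(min_read_length - INDEX_LENGTH, 1))
        if hit is None:
            triage.failed_match += 1
            continue
        gene, orientation = hit
        allele = extract_allele(
            body, ref_by_gene[gene], orientation, flank_len, max_flank_mismatch
        )
        if allele in ("missing", "neither"):
            triage.missing_msnp_base += 1
            continue
        triage.usable += 1
        counts[(sample, gene)][allele] += 1

    triage.read_length_histogram = dict(hist)
    rows = []
    exclusions: list[dict] = []
    het: set | None = None
    genotyped_samples: set | None = None
    if genotypes is not None:
        het = set(
            zip(
                genotypes.loc[genotypes["genotype"] == "Mm", "sample_id"],
                genotypes.loc[genotypes["genotype"] == "Mm", "gene"],
            )
        )
        genotyped_samples = set(genotypes["sample_id"])
    for (sample, gene), c in sorted(counts.items()):
        n_reads = c["M"] + c["m"]
        if genotypes is not None:
            if sample not in genotyped_samples:
                exclusions.append(
                    {"sample_id": sample, "gene": gene, "reason": "sample_not_genotyped",
                     "reads": n_reads}
                )
                continue
            if (sample, gene) not in het:
                exclusions.append(
                    {"sample_id": sample, "gene": gene, "reason": "not_heterozygous",
                     "reads": n_reads}
                )
                continue
        single = c["M"] == 0 or c["m"] == 0
        if single:
            triage.single_allele_only += n_reads
        rows.append(
            {
                "sample_id": sample,
                "gene": gene,
                "template": template,
                "count_M": c["M"],
                "count_m": c["m"],
                "single_allele_only": single,
            }
        )
    if het is not None:
        seen = {(r["sample_id"], r["gene"]) for r in rows}
        known_genes = set(ref_by_gene)
        known_samples = {i.sample_id for i in indices}
        for sample, gene in sorted(het):
            if gene in known_genes and sample in known_samples and (sample, gene) not in seen:
                exclusions.append(
                    {"sample_id": sample, "gene": gene, "reason": "no_usable_reads",
                     "reads": 0}
                )
    triage.validate()
    counts_df = pd.DataFrame(
        rows,
        columns=["sample_id", "gene", "template", "count_M", "count_m",
                 "single_allele_only"],
    )
    return CountResult(counts=counts_df, triage=triage, exclusions=exclusions)


def tabulate_counts(assigned, template: str = "cDNA",
                    genotypes: pd.DataFrame | None = None) -> CountResult:
    """Tabulate pre-assigned reads into allele-count records.

    ``assigned`` is an iterable of (sample_id, gene, allele) triples where
    allele is 'M', 'm', 'missing', 'neither' or None (None = failed match).
    Provided for pipelines that separate assignment from tabulation; the
    combined path is :func:`count_reads`.
    """
    triage = TriageReport()
    counts: dict[tuple[str, str], dict[str, int]] = defaultdict(lambda: {"M": 0, "m": 0})
    for sample, gene, allele in assigned:
        triage.total_reads += 1
        if allele is None or sample is None or gene is None:
            triage.failed_match += 1
        elif allele in ("missing", "neither"):
            triage.missing_msnp_base += 1
        elif allele in ("M", "m"):
            triage.usable += 1
            counts[(sample, gene)][allele] += 1
        else:
            raise ValueError(f"unknown allele label {allele!r}")
    rows = []
    het = None
    if genotypes is not None:
        het = set(
            zip(
                genotypes.loc[genotypes["genotype"] == "Mm", "sample_id"],
                genotypes.loc[genotypes["genotype"] == "Mm", "gene"],
            )
        )
    exclusions = []
    for (sample, gene), c in sorted(counts.items()):
        if het is not None and (sample, gene) not in het:
            exclusions.append({"sample_id": sample, "gene": gene,
                               "reason": "not_heterozygous", "reads": c["M"] + c["m"]})
            continue
        single = c["M"] == 0 or c["m"] == 0
        if single:
            triage.single_allele_only += c["M"] + c["m"]
        rows.append({"sample_id": sample, "gene": gene, "template": template,
                     "count_M": c["M"], "count_m": c["m"], "single_allele_only": single})
    triage.validate()
    return CountResult(
        counts=pd.DataFrame(rows, columns=["sample_id", "gene", "template", "count_M",
                                           "count_m", "single_allele_only"]),
        triage=triage,
        exclusions=exclusions,
    )


# ---------------------------------------------------------------------------
# TSV interfaces

def load_reference(path) -> list[AmpliconReference]:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return [
        AmpliconReference(
            gene=r.gene,
            amplicon_seq=r.amplicon_seq,
            msnp_offset=int(r.msnp_offset),
            allele_M=r.allele_M,
            allele_m=r.allele_m,
            numerator_allele=r.numerator_allele,
        )
        for r in df.itertuples()
    ]


def write_reference(references, path) -> None:
    pd.DataFrame(
        [
            {
                "gene": r.gene,
                "amplicon_seq": r.amplicon_seq,
                "msnp_offset": r.msnp_offset,
                "allele_M": r.allele_M,
                "allele_m": r.allele_m,
                "numerator_allele": r.numerator_allele,
            }
            for r in references
        ]
    ).to_csv(path, sep="\t", index=False)


def load_index_map(path) -> list[SampleIndex]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    indices = [SampleIndex(r.sample_id, r.index_seq) for r in df.itertuples()]
    seqs = [i.index_seq for i in indices]
    if len(set(seqs)) != len(seqs):
        raise ValueError("index map contains duplicate index sequences")
    return indices


def write_index_map(indices, path) -> None:
    pd.DataFrame(
        [{"sample_id": i.sample_id, "index_seq": i.index_seq} for i in indices]
    ).to_csv(path, sep="\t", index=False)


def load_genotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    bad = set(df["genotype"]) - {"MM", "Mm", "mm"}
    if bad:
        raise ValueError(f"invalid genotype labels: {sorted(bad)}")
    return df


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"sample_id": str, "gene": str, "template": str,
               "count_M": np.int64, "count_m": np.int64},
    )


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)
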