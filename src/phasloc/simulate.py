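"""Seeded synthetic scenarios with ground-truth manifests.

Every pipeline stage can be exercised without any real sequencing data:
the generator plants a PHAS locus (phased k-nt duplexes with the 2-nt
3'-overhang geometry, a complementary trigger whose cleavage site sets
the register, and a degradome tag pileup at that site) inside random
background, draws Poisson read depths, sprinkles out-of-phase noise, and
records everything planted in a JSON-serialisable manifest so tests can
demand exact recovery.

Default parameters are the study conditions used throughout: k = 21,
8 occupied duplexes, Poisson depth 20 per duplex strand, 10% out-of-phase
noise, 1-kb precursor among three 800-nt background transcripts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seq_io import (
    SequenceRecord,
    SmallRNALibrary,
    SmallRNARead,
    revcomp,
    to_rna,
    write_fasta,
    write_srna_library,
)
from .tasirna import PhasiRNA, enumerate_phasirnas

BASES = np.array(list("ACGT"))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    """I.i.d. uniform A/C/G/T background sequence."""
    return "".join(BASES[rng.integers(0, 4, size=length)])


@dataclass
class PhasScenario:
    """A planted-locus (or noise-only) small-RNA scenario."""

    transcripts: list[SequenceRecord]
    srna: SmallRNALibrary
    degradome: SmallRNALibrary
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.transcripts, outdir / "transcripts.fasta")
        write_srna_library(self.srna, outdir / "srna.tsv")
        write_srna_library(self.degradome, outdir / "degradome.tsv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _add_read(counts: dict[str, int], seq: str, count: int) -> None:
    if count > 0:
        counts[seq] = counts.get(seq, 0) + count


def make_phas_scenario(
    seed: int,
    k: int = 21,
    n_duplexes: int = 8,
    depth: float = 20.0,
    noise_rate: float = 0.1,
    transcript_len: int = 1000,
    n_background: int = 3,
    background_len: int = 800,
    degradome_depth: float = 20.0,
    n_degradome_background: int = 20,
    tag_len: int = 20,
    trigger_len: int = 21,
    planted: bool = True,
) -> PhasScenario:
    """Generate one PHAS discovery scenario.

    With ``planted=False`` the same number of reads is scattered with no
    phase structure (negative control: no candidate region should
    survive default thresholds).
    """
    if k not in (21, 24):
        raise ValueError("k must be 21 or 24")
    if planted and n_duplexes < 5:
        raise ValueError("a planted locus needs at least 5 duplexes")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must be in [0, 1]")

    rng = np.random.default_rng(seed)
    phas_id = "PHAS_T1"
    transcripts = [
        SequenceRecord(phas_id, random_sequence(rng, transcript_len))
    ]
    for i in range(n_background):
        transcripts.append(
            SequenceRecord(f"BG_T{i + 1}", random_sequence(rng, background_len))
        )
    phas_seq = transcripts[0].sequence

    srna_counts: dict[str, int] = {}
    deg_counts: dict[str, int] = {}
    manifest: dict = {
        "seed": int(seed),
        "k": k,
        "planted": planted,
        "phas_transcript": phas_id,
        "n_duplexes": n_duplexes,
        "depth": depth,
        "noise_rate": noise_rate,
    }

    n_phased_expected = int(round(2 * n_duplexes * depth))
    if planted:
        # anchor leaves room for the trigger binding site upstream
        # (binding_start = anchor - trigger_len + 10) and the full grid
        # plus the bottom-strand overhang downstream.
        lo = trigger_len - 9 + 2
        hi = transcript_len - n_duplexes * k + 1
        anchor = int(rng.integers(lo, hi - k))
        region_start = anchor
        region_end = anchor + n_duplexes * k - 1

        # phased duplex reads, both strands
        n_phased = 0
        for i in range(n_duplexes):
            top_start = anchor + i * k
            top = phas_seq[top_start - 1 : top_start + k - 1]
            bottom = revcomp(phas_seq[top_start - 3 : top_start + k - 3])
            for seq in (top, bottom):
                c = int(rng.poisson(depth))
                _add_read(srna_counts, seq, c)
                n_phased += c

        # trigger: complementary to [anchor - L + 10, anchor + 9], so its
        # position 10 faces the anchor nucleotide (cleavage site = anchor)
        binding_start = anchor - trigger_len + 10
        binding_end = anchor + 9
        trigger = revcomp(phas_seq[binding_start - 1 : binding_end])
        _add_read(srna_counts, trigger, int(rng.poisson(depth)) + 1)

        # degradome pileup at the cleavage site over sparse background
        tag = phas_seq[anchor - 1 : anchor - 1 + tag_len]
        _add_read(deg_counts, tag, max(1, int(rng.poisson(degradome_depth))))

        manifest.update(
            anchor=anchor,
            region_start=region_start,
            region_end=region_end,
            trigger_sequence=to_rna(trigger),
            binding_start=binding_start,
            binding_end=binding_end,
            cleavage_site=anchor,
        )
        n_noise = int(round(noise_rate * n_phased))
    else:
        # the noise process is identical to the planted scenario's; only
        # the locus (and its reads) is absent
        anchor = None
        n_noise = int(round(noise_rate * n_phased_expected))

    # out-of-phase (or unstructured) noise reads: unique k-mers, count 1
    placed = 0
    while placed < n_noise:
        pos = int(rng.integers(1, transcript_len - k + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if planted:
            fp = pos if strand == "+" else pos + k - 1
            off = (fp - anchor) % k
            in_phase = off == 0 if strand == "+" else off == (k - 3) % k
            if in_phase:
                continue
        seq = phas_seq[pos - 1 : pos + k - 1]
        if strand == "-":
            seq = revcomp(seq)
        _add_read(srna_counts, seq, 1)
        placed += 1

    # degradome background: scattered single tags away from the cleavage site
    placed = 0
    while placed < n_degradome_background:
        pos = int(rng.integers(1, transcript_len - tag_len + 1))
        if planted and pos == anchor:
            continue
        _add_read(deg_counts, phas_seq[pos - 1 : pos - 1 + tag_len], 1)
        placed += 1

    srna = SmallRNALibrary(
        name="synthetic_srna",
        reads={s: SmallRNARead(s, c) for s, c in srna_counts.items()},
    )
    degradome = SmallRNALibrary(
        name="synthetic_degradome",
        reads={s: SmallRNARead(s, c) for s, c in deg_counts.items()},
    )
    manifest["srna_total"] = srna.total_count
    manifest["degradome_total"] = degradome.total_count
    return PhasScenario(transcripts, srna, degradome, manifest)


def planted_phased_sequences(scenario: PhasScenario) -> set[str]:
    """Sequences of the planted in-phase duplex reads (both strands)."""
    m = scenario.manifest
    if not m.get("planted"):
        return set()
    phas_seq = next(
        t for t in scenario.transcripts if t.id == m["phas_transcript"]
    ).sequence
    k, anchor = m["k"], m["anchor"]
    out: set[str] = set()
    for i in range(m["n_duplexes"]):
        top_start = anchor + i * k
        out.add(phas_seq[top_start - 1 : top_start + k - 1])
        out.add(revcomp(phas_seq[top_start - 3 : top_start + k - 3]))
    return out


def make_mutant_library(
    wt: SmallRNALibrary,
    depletion: float,
    seed: int,
    phased_sequences: set[str],
) -> SmallRNALibrary:
    """Emulate a dcl-mutant library by binomially thinning phased reads.

    Each phased read's count is kept with probability ``depletion``
    (0 = phasiRNAs absent, 1 = library unchanged); background reads pass
    through untouched.
    """
    if not 0.0 <= depletion <= 1.0:
        raise ValueError("depletion factor must be in [0, 1]")
    rng = np.random.default_rng(seed)
    reads: dict[str, SmallRNARead] = {}
    for seq, read in wt.reads.items():
        if seq in phased_sequences:
            count = int(rng.binomial(read.count, depletion))
        else:
            count = read.count
        if count > 0:
            reads[seq] = SmallRNARead(seq, count)
    return SmallRNALibrary(name=f"{wt.name}_mutant", reads=reads)


@dataclass
class RdDMScenario:
    """Promoter-methylation scenario for the RdDM stage."""

    precursor: SequenceRecord
    phasirnas: list[PhasiRNA]
    promoters: list[SequenceRecord]
    cdnas: list[SequenceRecord]
    bisulfite: dict[str, SmallRNALibrary]  # tissue -> library
    rnaseq: dict[str, SmallRNALibrary]
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.promoters, outdir / "promoters.fasta")
        write_fasta(self.cdnas, outdir / "cdnas.fasta")
        with open(outdir / "phasirnas.tsv", "w") as fh:
            fh.write("name\tsequence\n")
            for p in self.phasirnas:
                fh.write(f"{p.name}\t{p.rna_sequence}\n")
        for tissue, lib in self.bisulfite.items():
            write_srna_library(lib, outdir / f"bisulfite_{tissue}.tsv")
        for tissue, lib in self.rnaseq.items():
            write_srna_library(lib, outdir / f"rnaseq_{tissue}.tsv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def _bisulfite_read(
    rng: np.random.Generator,
    promoter: str,
    start: int,
    length: int,
    strand: str,
    meth_rates: dict[str, float],
    conversion: float,
    contexts: dict[tuple[int, str], str],
) -> str:
    """Draw one bisulfite read (5'->3' on its own strand)."""
    window = promoter[start - 1 : start - 1 + length]
    native = window if strand == "+" else revcomp(window)
    out = []
    for i, base in enumerate(native):
        if base != "C":
            out.append(base)
            continue
        pos = start + i if strand == "+" else start + length - 1 - i
        context = contexts[(pos, strand)]
        if rng.random() < meth_rates[context]:
            out.append("C")  # methylated: protected from conversion
        elif rng.random() < conversion:
            out.append("T")
        else:
            out.append("C")  # conversion failure
    return "".join(out)


def make_rddm_scenario(
    seed: int,
    n_phasirnas: int = 2,
    promoter_len: int = 200,
    precursor_len: int = 400,
    cdna_len: int = 300,
    bis_read_len: int = 60,
    n_bis_reads: int = 60,
    conversion: float = 1.0,
    meth_rates: dict[str, dict[str, float]] | None = None,
    target_depth: dict[str, int] | None = None,
    expressing_tissue: str = "panicle",
    other_tissue: str = "root",
) -> RdDMScenario:
    """Generate a two-tissue RdDM scenario around one target promoter.

    24-nt phasiRNAs are enumerated from a planted precursor and their
    reverse complements planted in the promoter; bisulfite reads carry
    per-context methylation (defaults: CHH 0.6 in the phasiRNA-expressing
    tissue vs 0.05 in the other, CG/CHG equal across tissues) and the
    target gene's RNA-seq depth is lower where methylation is high.
    """
    if meth_rates is None:
        meth_rates = {
            expressing_tissue: {"CG": 0.3, "CHG": 0.2, "CHH": 0.6},
            other_tissue: {"CG": 0.3, "CHG": 0.2, "CHH": 0.05},
        }
    if target_depth is None:
        target_depth = {expressing_tissue: 5, other_tissue: 40}

    rng = np.random.default_rng(seed)
    precursor = SequenceRecord("PHAS24_T1", random_sequence(rng, precursor_len))
    anchor = precursor_len // 2
    enumerated = enumerate_phasirnas(precursor, anchor, 24, arm="3'")
    phasirnas = [p for p in enumerated if p.strand == "+"][:n_phasirnas]
    if len(phasirnas) < n_phasirnas:
        raise ValueError("precursor too short for requested phasiRNA count")

    promoter_seq = list(random_sequence(rng, promoter_len))
    gap = promoter_len // (n_phasirnas + 1)
    planted_hits = []
    for j, p in enumerate(phasirnas):
        start = 1 + (j + 1) * gap - 24
        site = revcomp(p.sequence)
        promoter_seq[start - 1 : start + 23] = list(site)
        planted_hits.append(
            {"phasirna": p.name, "start": start, "end": start + 23}
        )
    promoter = SequenceRecord(
        "PROM_1", "".join(promoter_seq), kind="promoter"
    )

    # classify every cytosine context once, on the final promoter
    from .rddm import classify_context  # local import avoids a cycle

    contexts: dict[tuple[int, str], str] = {}
    for pos, base in enumerate(promoter.sequence, start=1):
        if base == "C":
            contexts[(pos, "+")] = classify_context(promoter.sequence, pos, "+")
        if base == "G":
            contexts[(pos, "-")] = classify_context(promoter.sequence, pos, "-")

    target = SequenceRecord("TARGET_G1", random_sequence(rng, cdna_len))
    decoy = SequenceRecord("DECOY_G1", random_sequence(rng, cdna_len))

    bisulfite: dict[str, SmallRNALibrary] = {}
    rnaseq: dict[str, SmallRNALibrary] = {}
    for tissue in (expressing_tissue, other_tissue):
        counts: dict[str, int] = {}
        for _ in range(n_bis_reads):
            start = int(rng.integers(1, promoter_len - bis_read_len + 2))
            strand = "+" if rng.random() < 0.5 else "-"
            seq = _bisulfite_read(
                rng, promoter.sequence, start, bis_read_len, strand,
                meth_rates[tissue], conversion, contexts,
            )
            _add_read(counts, seq, 1)
        bisulfite[tissue] = SmallRNALibrary(
            name=f"bisulfite_{tissue}",
            reads={s: SmallRNARead(s, c) for s, c in counts.items()},
            total_count=n_bis_reads,
        )

        rna_counts: dict[str, int] = {}
        read_len = 50
        for _ in range(target_depth[tissue]):
            start = int(rng.integers(1, cdna_len - read_len + 2))
            _add_read(rna_counts, target.sequence[start - 1 : start - 1 + read_len], 1)
        for _ in range(60):  # decoy background keeps library sizes comparable
            start = int(rng.integers(1, cdna_len - read_len + 2))
            _add_read(rna_counts, decoy.sequence[start - 1 : start - 1 + read_len], 1)
        rnaseq[tissue] = SmallRNALibrary(
            name=f"rnaseq_{tissue}",
            reads={s: SmallRNARead(s, c) for s, c in rna_counts.items()},
        )

    manifest = {
        "seed": int(seed),
        "promoter": promoter.id,
        "target_gene": target.id,
        "promoter_target_map": {promoter.id: target.id},
        "planted_hits": planted_hits,
        "meth_rates": meth_rates,
        "conversion": conversion,
        "target_depth": target_depth,
        "expressing_tissue": expressing_tissue,
        "other_tissue": other_tissue,
        "phasirnas": [
            {"name": p.name, "sequence": p.rna_sequence} for p in phasirnas
        ],
    }
    return RdDMScenario(
        precursor=precursor,
        phasirnas=phasirnas,
        promoters=[promoter],
        cdnas=[target, decoy],
        bisulfite=bisulfite,
        rnaseq=rnaseq,
        manifest=manifest,
    )
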