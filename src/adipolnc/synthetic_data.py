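"""Truth-labeled synthetic inputs for the whole pipeline.

The generator emulates the structure of a merged-assembly adipocyte
RNA-seq study: three cell types (white, brown, beige) with two
replicates each, a reference annotation of multi-exon coding genes and
annotated lncRNAs (including single-exon loci), and unannotated
transcripts among which a planted subset satisfies every novelty
criterion while each decoy violates exactly one.  Planted labels cover
transcript class, per-group differential-expression effects, and two
demonstration cis pairs (a downstream/antisense and an upstream/sense
configuration).

Everything is drawn from one seeded generator, so a seed fixes the
output byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .models import (
    ANNOTATED_LNCRNA,
    CODING,
    UNANNOTATED,
    ExonInterval,
    GenomeAnnotation,
    SequenceRecord,
    TranscriptModel,
)

PathLike = Union[str, Path]

TRUE_NOVEL = "true_novel"
DECOY_SHORT = "decoy:short"
DECOY_LOW_FPKM = "decoy:low_fpkm"
DECOY_EXON_OVERLAP = "decoy:exon_overlap"
DECOY_NEAR_SINGLE_EXON = "decoy:near_single_exon"
DECOY_CODING_POTENTIAL = "decoy:coding_potential"
DECOY_CLASSES = (
    DECOY_SHORT,
    DECOY_LOW_FPKM,
    DECOY_EXON_OVERLAP,
    DECOY_NEAR_SINGLE_EXON,
    DECOY_CODING_POTENTIAL,
)

SAMPLE_GROUPS: Dict[str, List[str]] = {
    "White": ["White-1", "White-2"],
    "Brown": ["Brown-1", "Brown-2"],
    "Beige": ["Beige-1", "Beige-2"],
}
SAMPLES = [s for group in SAMPLE_GROUPS.values() for s in group]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# one preferred codon per amino acid (lexicographically first), heavily
# overweighted so coding ORFs carry a strong, learnable hexamer bias
_SENSE_CODONS: List[str] = []
_STOPS = {"TAA", "TAG", "TGA"}
for _a in "ACGT":
    for _b in "ACGT":
        for _c in "ACGT":
            cod = _a + _b + _c
            if cod not in _STOPS:
                _SENSE_CODONS.append(cod)

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "AGT": "S", "AGC": "S", "CCT": "P", "CCC": "P",
    "CCA": "P", "CCG": "P", "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
_PREFERRED = {}
for _cod in sorted(_CODON_TABLE):
    _PREFERRED.setdefault(_CODON_TABLE[_cod], _cod)
_CODON_WEIGHTS = np.array(
    [8.0 if _PREFERRED[_CODON_TABLE[c]] == c else 1.0 for c in _SENSE_CODONS]
)
_CODON_WEIGHTS /= _CODON_WEIGHTS.sum()


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark.

    Defaults encode the benchmark conditions: 50 planted novel lncRNAs,
    10 single-violation decoys per criterion, reference classes large
    enough to train the coding-potential scorer, and a 3 cell type × 2
    replicate negative-binomial count design.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 2_200_000
    n_coding_genes: int = 300
    n_annotated_lncrnas: int = 160   # multi-exon annotated lncRNAs
    n_single_exon_known: int = 40    # single-exon annotated lncRNA loci
    n_true_novel: int = 50
    decoy_counts: Dict[str, int] = field(
        default_factory=lambda: {c: 10 for c in DECOY_CLASSES}
    )
    # negative-binomial expression model
    nb_dispersion: float = 0.1
    log_baseline_coding: float = 5.0      # ln-scale mean of baseline counts
    log_baseline_novel: float = 4.1
    log_baseline_annotated_lnc: float = 3.2
    log_baseline_sd: float = 0.6
    size_factor_sd: float = 0.15
    de_fraction: float = 0.2              # fraction of expressed features with a group effect
    de_log2fc: float = 3.0                # magnitude of planted effects
    de_two_group_fraction: float = 0.3    # DE features with opposing effects in two groups
    # conservation track (beta-distribution parameters per region class)
    cons_coding_exon: Tuple[float, float] = (8.0, 2.0)
    cons_lncrna_exon: Tuple[float, float] = (3.0, 7.0)
    cons_intron: Tuple[float, float] = (2.0, 8.0)
    cons_window: int = 100
    # term map
    n_terms: int = 30
    term_size_range: Tuple[int, int] = (10, 40)

    def to_json(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: PathLike) -> "SimulationConfig":
        payload = json.loads(Path(path).read_text())
        for key in ("cons_coding_exon", "cons_lncrna_exon", "cons_intron", "term_size_range"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class SimulationTruth:
    """Planted ground truth for every simulated feature."""

    features: pd.DataFrame        # indexed by feature_id
    cis_pairs: pd.DataFrame
    config: SimulationConfig
    size_factors: Optional[pd.Series] = None

    def true_novel_ids(self) -> List[str]:
        return list(self.features.index[self.features["label"] == TRUE_NOVEL])

    def decoy_ids(self) -> List[str]:
        mask = self.features["label"].str.startswith("decoy:")
        return list(self.features.index[mask])

    def ids_with_label(self, label: str) -> List[str]:
        return list(self.features.index[self.features["label"] == label])

    def lncrna_like_ids(self) -> List[str]:
        mask = self.features["label"].isin([ANNOTATED_LNCRNA, TRUE_NOVEL])
        return list(self.features.index[mask])

    def true_lfc(self, group_a: str, group_b: str) -> pd.Series:
        """Planted log2 fold change of group_a over group_b per feature."""
        return (
            self.features[f"effect_{group_a}"].fillna(0.0)
            - self.features[f"effect_{group_b}"].fillna(0.0)
        )


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _coding_mrna(rng: np.random.Generator, n_codons: int,
                 utr5: int, utr3: int) -> str:
    """mRNA with a codon-biased ORF spanning the body of the transcript."""
    codons = rng.choice(len(_SENSE_CODONS), size=n_codons, p=_CODON_WEIGHTS)
    orf = "ATG" + "".join(_SENSE_CODONS[i] for i in codons) + "TAA"
    return _random_bases(rng, utr5) + orf + _random_bases(rng, utr3)


def _noncoding_rna(rng: np.random.Generator, length: int,
                   max_orf_coverage: float = 0.5, max_tries: int = 60) -> str:
    """Random-composition sequence whose longest ORF covers at most
    ``max_orf_coverage`` of the transcript (rejection-sampled)."""
    from .coding_potential import find_longest_orf

    for _ in range(max_tries):
        seq = _random_bases(rng, length)
        if find_longest_orf(seq).orf_coverage <= max_orf_coverage:
            return seq
    raise SimulationError(
        f"could not draw a low-ORF sequence of length {length}"
    )


def _split_exons(rng: np.random.Generator, length: int, n_exons: int,
                 min_exon: int = 30) -> List[int]:
    """Partition a spliced length into exon lengths, each >= min_exon."""
    n_exons = max(1, min(n_exons, length // (2 * min_exon)))
    if n_exons == 1:
        return [length]
    extra = length - n_exons * min_exon
    weights = rng.random(n_exons)
    alloc = np.floor(extra * weights / weights.sum()).astype(int)
    alloc[0] += extra - alloc.sum()
    return [int(min_exon + a) for a in alloc]


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class _Locus:
    """One transcript to place: spliced sequence + exon/intron layout."""

    transcript_id: str
    gene_id: str
    label: str
    status: str
    seq: str
    exon_lengths: List[int]
    intron_lengths: List[int]
    strand: str

    @property
    def footprint(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    def place(self, chrom: str, start: int) -> Tuple[TranscriptModel, List[Tuple[int, int, str]]]:
        """Materialize at a genomic position.

        Returns the transcript model and the genomic (start, end, piece)
        segments to paste into the genome.
        """
        genomic_seq = self.seq if self.strand == "+" else _revcomp(self.seq)
        exons = []
        pieces = []
        pos = start
        offset = 0
        for i, elen in enumerate(self.exon_lengths):
            exons.append(
                ExonInterval(chrom=chrom, start=pos, end=pos + elen, strand=self.strand)
            )
            pieces.append((pos, pos + elen, genomic_seq[offset : offset + elen]))
            offset += elen
            pos += elen
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        model = TranscriptModel(
            transcript_id=self.transcript_id,
            gene_id=self.gene_id,
            exons=tuple(exons),
            annotation_status=self.status,
        )
        return model, pieces


def _make_locus(
    rng: np.random.Generator,
    transcript_id: str,
    gene_id: str,
    label: str,
    status: str,
    seq: str,
    n_exons: int,
    strand: Optional[str] = None,
) -> _Locus:
    exon_lengths = _split_exons(rng, len(seq), n_exons)
    intron_lengths = [int(rng.integers(100, 800)) for _ in exon_lengths[:-1]]
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    return _Locus(
        transcript_id=transcript_id,
        gene_id=gene_id,
        label=label,
        status=status,
        seq=seq,
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        strand=strand,
    )


# ---------------------------------------------------------------------------
# annotation simulation
# ---------------------------------------------------------------------------

def simulate_annotation(
    cfg: SimulationConfig,
) -> Tuple[GenomeAnnotation, GenomeAnnotation, Dict[str, SequenceRecord], SimulationTruth]:
    """Build (reference, assembled, genome, truth).

    The assembled annotation is the reference plus the unannotated
    transcripts (merged-assembly convention).  True-novel transcripts
    satisfy every novelty criterion by construction; each decoy class
    violates exactly its designated criterion:

    - ``decoy:short`` — spliced length <= 200 nt
    - ``decoy:low_fpkm`` — zero planted expression
    - ``decoy:exon_overlap`` — shares exonic bases with an annotated lncRNA
    - ``decoy:near_single_exon`` — within 2 kb of a known single-exon locus
    - ``decoy:coding_potential`` — codon-biased ORF spanning the transcript
    """
    rng = np.random.default_rng([cfg.seed, 101])

    # --- draw all loci -----------------------------------------------------
    blocks: List[Dict] = []  # {"loci": [(locus, gap_after_within_block)], "flank": bp}

    def simple_block(locus: _Locus, flank: Optional[int] = None) -> Dict:
        return {"loci": [(locus, 0)], "flank": flank}

    mstrg_counter = 1

    def mstrg_id() -> Tuple[str, str]:
        nonlocal mstrg_counter
        gid = f"MSTRG.{mstrg_counter}"
        mstrg_counter += 1
        return f"{gid}.1", gid

    coding_loci: List[_Locus] = []
    for i in range(cfg.n_coding_genes):
        n_codons = int(rng.integers(150, 450))
        seq = _coding_mrna(
            rng, n_codons, utr5=int(rng.integers(30, 120)), utr3=int(rng.integers(50, 250))
        )
        locus = _make_locus(
            rng, f"TCOD{i:05d}", f"GCOD{i:05d}", CODING, CODING, seq,
            n_exons=int(rng.integers(3, 9)),
        )
        coding_loci.append(locus)

    lnc_loci: List[_Locus] = []
    for i in range(cfg.n_annotated_lncrnas):
        length = int(np.clip(rng.lognormal(np.log(600), 0.4), 250, 3000))
        seq = _noncoding_rna(rng, length)
        lnc_loci.append(
            _make_locus(
                rng, f"TLNC{i:05d}", f"GLNC{i:05d}", ANNOTATED_LNCRNA,
                ANNOTATED_LNCRNA, seq, n_exons=int(rng.integers(2, 5)),
            )
        )

    single_loci: List[_Locus] = []
    for i in range(cfg.n_single_exon_known):
        length = int(np.clip(rng.lognormal(np.log(500), 0.4), 220, 2000))
        seq = _noncoding_rna(rng, length)
        single_loci.append(
            _make_locus(
                rng, f"TSGL{i:05d}", f"GSGL{i:05d}", ANNOTATED_LNCRNA,
                ANNOTATED_LNCRNA, seq, n_exons=1,
            )
        )

    novel_loci: List[_Locus] = []
    for i in range(cfg.n_true_novel):
        length = int(np.clip(rng.lognormal(np.log(700), 0.4), 300, 3000))
        seq = _noncoding_rna(rng, length)
        tid, gid = mstrg_id()
        novel_loci.append(
            _make_locus(
                rng, tid, gid, TRUE_NOVEL, UNANNOTATED, seq,
                n_exons=int(rng.integers(2, 5)),
            )
        )

    decoys: Dict[str, List[_Locus]] = {c: [] for c in DECOY_CLASSES}
    for _ in range(cfg.decoy_counts.get(DECOY_SHORT, 0)):
        tid, gid = mstrg_id()
        seq = _noncoding_rna(rng, int(rng.integers(120, 201)))
        decoys[DECOY_SHORT].append(
            _make_locus(rng, tid, gid, DECOY_SHORT, UNANNOTATED, seq, n_exons=1)
        )
    for _ in range(cfg.decoy_counts.get(DECOY_LOW_FPKM, 0)):
        tid, gid = mstrg_id()
        seq = _noncoding_rna(rng, int(np.clip(rng.lognormal(np.log(700), 0.4), 300, 3000)))
        decoys[DECOY_LOW_FPKM].append(
            _make_locus(rng, tid, gid, DECOY_LOW_FPKM, UNANNOTATED, seq, n_exons=2)
        )
    for _ in range(cfg.decoy_counts.get(DECOY_NEAR_SINGLE_EXON, 0)):
        tid, gid = mstrg_id()
        seq = _noncoding_rna(rng, int(np.clip(rng.lognormal(np.log(700), 0.4), 300, 2000)))
        decoys[DECOY_NEAR_SINGLE_EXON].append(
            _make_locus(rng, tid, gid, DECOY_NEAR_SINGLE_EXON, UNANNOTATED, seq, n_exons=2)
        )
    for _ in range(cfg.decoy_counts.get(DECOY_CODING_POTENTIAL, 0)):
        tid, gid = mstrg_id()
        seq = _coding_mrna(
            rng, int(rng.integers(120, 300)), utr5=int(rng.integers(10, 40)),
            utr3=int(rng.integers(10, 60)),
        )
        decoys[DECOY_CODING_POTENTIAL].append(
            _make_locus(rng, tid, gid, DECOY_CODING_POTENTIAL, UNANNOTATED, seq, n_exons=2)
        )
    # exon-overlap decoys are built against host lncRNAs below
    n_overlap = cfg.decoy_counts.get(DECOY_EXON_OVERLAP, 0)
    if n_overlap > len(lnc_loci):
        raise SimulationError("not enough annotated lncRNAs to host overlap decoys")
    n_near = len(decoys[DECOY_NEAR_SINGLE_EXON])
    if n_near > len(single_loci):
        raise SimulationError("not enough single-exon loci for near-single-exon decoys")

    # --- assemble blocks ---------------------------------------------------
    cis_records: List[Dict] = []

    # demonstration cis pair A: novel on "-" immediately downstream of a
    # "+" coding gene (the downstream/antisense configuration)
    gene_a = coding_loci[0]
    gene_a.strand = "+"
    novel_a = novel_loci[0]
    novel_a.strand = "-"
    blocks.append({"loci": [(gene_a, 1000), (novel_a, 0)], "flank": 6500})
    cis_records.append(
        {
            "lncrna_id": novel_a.transcript_id,
            "target_gene_id": gene_a.gene_id,
            "relative_position": "downstream",
            "relative_strand": "antisense",
            "planted_gap": 1000,
        }
    )
    # demonstration cis pair B: novel on "+" upstream of a "+" coding gene
    # (the upstream/sense configuration)
    gene_b = coding_loci[1]
    gene_b.strand = "+"
    novel_b = novel_loci[1]
    novel_b.strand = "+"
    blocks.append({"loci": [(novel_b, 4000), (gene_b, 0)], "flank": 6500})
    cis_records.append(
        {
            "lncrna_id": novel_b.transcript_id,
            "target_gene_id": gene_b.gene_id,
            "relative_position": "upstream",
            "relative_strand": "sense",
            "planted_gap": 4000,
        }
    )

    for locus in coding_loci[2:]:
        blocks.append(simple_block(locus))
    for locus in novel_loci[2:]:
        blocks.append(simple_block(locus))

    # near-single-exon decoys ride right behind a single-exon locus
    for i, decoy in enumerate(decoys[DECOY_NEAR_SINGLE_EXON]):
        gap = int(rng.integers(200, 1500))
        blocks.append({"loci": [(single_loci[i], gap), (decoy, 0)], "flank": None})
    for locus in single_loci[n_near:]:
        blocks.append(simple_block(locus))

    # overlap decoys share exonic bases with a host annotated lncRNA: one
    # exon that covers the tail of the host's first exon and runs on into
    # the host intron (whose bases are overwritten with a low-ORF draw)
    for i in range(n_overlap):
        host = lnc_loci[i]
        tid, gid = mstrg_id()
        own_len = int(rng.integers(260, 520))
        body = _noncoding_rna(rng, own_len - 60)
        decoy = _Locus(
            transcript_id=tid,
            gene_id=gid,
            label=DECOY_EXON_OVERLAP,
            status=UNANNOTATED,
            seq=body,  # pasted past the shared 60 bp after placement
            exon_lengths=[own_len],
            intron_lengths=[],
            strand="+",
        )
        decoys[DECOY_EXON_OVERLAP].append(decoy)
        blocks.append({"loci": [(host, 0)], "flank": None, "overlay": (decoy, own_len)})
    for locus in lnc_loci[n_overlap:]:
        blocks.append(simple_block(locus))

    for locus in decoys[DECOY_SHORT] + decoys[DECOY_LOW_FPKM] + decoys[DECOY_CODING_POTENTIAL]:
        blocks.append(simple_block(locus))

    # --- shuffle and place -------------------------------------------------
    order = rng.permutation(len(blocks))
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    genome_arrays = {
        c: np.frombuffer(
            _random_bases(rng, cfg.chromosome_length).encode(), dtype="S1"
        ).copy()
        for c in chrom_names
    }

    transcripts: List[TranscriptModel] = []
    locus_meta: List[Tuple[_Locus, TranscriptModel]] = []

    chrom_idx = 0
    cursor = int(rng.integers(3000, 6000))
    for bi in order:
        block = blocks[bi]
        flank = block.get("flank")
        gap_before = flank if flank else int(rng.integers(2500, 6000))
        block_footprint = sum(
            loc.footprint + gap for loc, gap in block["loci"]
        )
        overlay = block.get("overlay")
        if overlay is not None:
            block_footprint = max(block_footprint, overlay[1] + 60)
        needed = gap_before + block_footprint + (flank or 0)
        while cursor + needed > cfg.chromosome_length - 3000:
            chrom_idx += 1
            if chrom_idx >= len(chrom_names):
                raise SimulationError(
                    "genome too small for the requested loci; increase "
                    "chromosome_length or n_chromosomes"
                )
            cursor = int(rng.integers(3000, 6000))
        chrom = chrom_names[chrom_idx]
        cursor += gap_before
        for loc, gap_after in block["loci"]:
            model, pieces = loc.place(chrom, cursor)
            for s, e, piece in pieces:
                genome_arrays[chrom][s:e] = np.frombuffer(piece.encode(), dtype="S1")
            transcripts.append(model)
            locus_meta.append((loc, model))
            cursor = model.span[1] + gap_after
        if overlay is not None:
            decoy, own_len = overlay
            host_model = transcripts[-1]
            host_first = host_model.exons[0]
            # one exon starting inside the host's first exon: guaranteed
            # >= 1 bp of exonic overlap, extending past it
            start = host_first.end - 60
            model = TranscriptModel(
                transcript_id=decoy.transcript_id,
                gene_id=decoy.gene_id,
                exons=(
                    ExonInterval(
                        chrom=chrom, start=start, end=start + own_len, strand="+"
                    ),
                ),
                annotation_status=UNANNOTATED,
            )
            # keep the shared 60 bp of host exon; overwrite the rest with
            # the low-ORF body so the decoy violates only the overlap rule
            body = np.frombuffer(decoy.seq.encode(), dtype="S1")
            genome_arrays[chrom][host_first.end : start + own_len] = body
            transcripts.append(model)
            locus_meta.append((decoy, model))
            cursor = max(cursor, model.span[1])
        if flank:
            cursor += flank

    genome = {
        c: SequenceRecord(id=c, sequence=arr.tobytes().decode())
        for c, arr in genome_arrays.items()
    }

    reference = GenomeAnnotation(
        t for t in transcripts if t.annotation_status != UNANNOTATED
    )
    assembled = GenomeAnnotation(transcripts)

    # --- expression truth --------------------------------------------------
    feat_rows = []
    groups = list(SAMPLE_GROUPS)
    log_baseline = {
        CODING: cfg.log_baseline_coding,
        TRUE_NOVEL: cfg.log_baseline_novel,
        ANNOTATED_LNCRNA: cfg.log_baseline_annotated_lnc,
        DECOY_SHORT: cfg.log_baseline_novel,
        DECOY_LOW_FPKM: None,
        DECOY_EXON_OVERLAP: cfg.log_baseline_novel,
        DECOY_NEAR_SINGLE_EXON: cfg.log_baseline_novel,
        DECOY_CODING_POTENTIAL: cfg.log_baseline_novel,
    }
    for loc, model in locus_meta:
        base_mu = log_baseline[loc.label]
        if base_mu is None:
            q = 0.0
        else:
            q = float(np.exp(rng.normal(base_mu, cfg.log_baseline_sd)))
        effects = {g: 0.0 for g in groups}
        if q > 0 and rng.random() < cfg.de_fraction:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            first = groups[int(rng.integers(len(groups)))]
            effects[first] = sign * cfg.de_log2fc
            if rng.random() < cfg.de_two_group_fraction:
                # an opposing effect in a second group: such a feature is
                # differential in every pairwise contrast (a "common DEG")
                others = [g for g in groups if g != first]
                second = others[int(rng.integers(len(others)))]
                effects[second] = -sign * cfg.de_log2fc
        s, e = model.span
        feat_rows.append(
            {
                "feature_id": model.transcript_id,
                "label": loc.label,
                "gene_id": model.gene_id,
                "chrom": model.chrom,
                "strand": model.strand,
                "start": s,
                "end": e,
                "length": model.length,
                "n_exons": model.n_exons,
                "baseline": q,
                **{f"effect_{g}": effects[g] for g in groups},
            }
        )
    # planted cis candidates are browning-responsive: high in beige only
    features = pd.DataFrame(feat_rows).set_index("feature_id")
    for rec in cis_records:
        for g in groups:
            features.loc[rec["lncrna_id"], f"effect_{g}"] = (
                cfg.de_log2fc if g == "Beige" else 0.0
            )

    truth = SimulationTruth(
        features=features,
        cis_pairs=pd.DataFrame(cis_records),
        config=cfg,
    )
    return reference, assembled, genome, truth


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean mu, dispersion alpha) via the gamma–Poisson mixture;
    Poisson when alpha == 0."""
    mu = np.asarray(mu, dtype=float)
    if alpha == 0:
        return rng.poisson(mu)
    lam = np.where(
        mu > 0, rng.gamma(shape=1.0 / alpha, scale=alpha * np.maximum(mu, 1e-300)), 0.0
    )
    return rng.poisson(lam)


def simulate_counts(
    truth: SimulationTruth, cfg: Optional[SimulationConfig] = None
) -> ExpressionMatrix:
    """NB counts for the 6-sample design; size factors recorded in truth.

    Mean of feature i in sample j is s_j · q_i · 2^lfc when sample j's
    group is the feature's affected group, else s_j · q_i.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 202])
    s = np.exp(rng.normal(0.0, cfg.size_factor_sd, size=len(SAMPLES)))
    s /= np.exp(np.log(s).mean())  # geometric mean 1
    size = pd.Series(s, index=SAMPLES, name="size_factor")

    q = truth.features["baseline"].to_numpy(dtype=float)
    effects = {
        g: truth.features[f"effect_{g}"].fillna(0.0).to_numpy(dtype=float)
        for g in SAMPLE_GROUPS
    }

    counts = np.zeros((len(q), len(SAMPLES)), dtype=np.int64)
    for j, sample in enumerate(SAMPLES):
        group = sample.rsplit("-", 1)[0]
        mu = q * 2.0 ** effects[group] * s[j]
        counts[:, j] = _nb_draw(rng, mu, cfg.nb_dispersion)

    frame = pd.DataFrame(counts, index=truth.features.index, columns=SAMPLES)
    truth.size_factors = size
    return ExpressionMatrix(
        counts=frame, sample_groups={g: list(m) for g, m in SAMPLE_GROUPS.items()}
    )


def simulate_nb_counts(
    rng: np.random.Generator,
    n_features: int,
    group_sizes: Sequence[int],
    dispersion: float = 0.1,
    log_mean: float = 5.0,
    log_sd: float = 1.0,
    lfc: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Bare two-or-more-group NB count matrix for calibration studies.

    ``lfc`` (per feature, applied to the first group) plants effects;
    None means global null.
    """
    q = np.exp(rng.normal(log_mean, log_sd, size=n_features))
    cols = []
    names = []
    for gi, size in enumerate(group_sizes):
        mu = q * (2.0 ** lfc if (gi == 0 and lfc is not None) else 1.0)
        for r in range(size):
            cols.append(_nb_draw(rng, mu, dispersion))
            names.append(f"g{gi}-{r + 1}")
    return pd.DataFrame(
        np.column_stack(cols),
        index=[f"f{i:05d}" for i in range(n_features)],
        columns=names,
    )


# ---------------------------------------------------------------------------
# conservation + term map
# ---------------------------------------------------------------------------

def simulate_conservation(
    truth: SimulationTruth,
    annotation: GenomeAnnotation,
    cfg: Optional[SimulationConfig] = None,
) -> pd.DataFrame:
    """Windowed conservation track covering exons and introns.

    Coding exons draw from a high-mean beta distribution, lncRNA exons
    from a low-mean one, and all introns from a lower one, so the
    canonical class ordering is recoverable.  Scores are in [0, 1].
    Returns a (chrom, start, end, score) frame sorted by position.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 303])
    rows: List[Tuple[str, int, int, float]] = []

    def emit(chrom: str, start: int, end: int, a: float, b: float) -> None:
        for ws in range(start, end, cfg.cons_window):
            we = min(ws + cfg.cons_window, end)
            rows.append((chrom, ws, we, float(rng.beta(a, b))))

    for t in sorted(annotation, key=lambda t: (t.chrom, t.span, t.transcript_id)):
        if t.annotation_status == CODING:
            a, b = cfg.cons_coding_exon
        else:
            a, b = cfg.cons_lncrna_exon
        for e in t.exons:
            emit(e.chrom, e.start, e.end, a, b)
        ia, ib = cfg.cons_intron
        for s, e in t.introns():
            emit(t.chrom, s, e, ia, ib)
    frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])
    return frame.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def simulate_term_map(
    truth: SimulationTruth, cfg: Optional[SimulationConfig] = None
) -> pd.DataFrame:
    """Gene→term annotation over the coding genes, with one term enriched
    among features carrying planted effects."""
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 404])
    coding = truth.features[truth.features["label"] == CODING]
    gene_ids = list(coding["gene_id"])
    any_effect = (
        coding[[f"effect_{g}" for g in SAMPLE_GROUPS]].abs().sum(axis=1) > 0
    )
    de_genes = list(coding.loc[any_effect, "gene_id"])
    rows = []
    for i in range(cfg.n_terms):
        size = int(rng.integers(*cfg.term_size_range))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)), replace=False)
        for g in members:
            rows.append((g, f"T{i:03d}", f"random term {i}"))
    # planted enriched term: predominantly planted-effect genes
    if de_genes:
        n_hit = min(25, len(de_genes))
        members = list(rng.choice(de_genes, size=n_hit, replace=False))
        members += list(rng.choice(gene_ids, size=5, replace=False))
        for g in sorted(set(members)):
            rows.append((g, "T_DE", "planted differential term"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])


# ---------------------------------------------------------------------------
# full emission
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimulationConfig, outdir: PathLike) -> Dict[str, Path]:
    """Generate and write every pipeline input plus the truth tables."""
    from .annotation_io import write_fasta, write_gtf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, assembled, genome, truth = simulate_annotation(cfg)
    counts = simulate_counts(truth, cfg)
    conservation = simulate_conservation(truth, assembled, cfg)
    term_map = simulate_term_map(truth, cfg)

    paths = {
        "reference_gtf": outdir / "reference.gtf",
        "assembled_gtf": outdir / "assembled.gtf",
        "genome_fasta": outdir / "genome.fa",
        "counts_tsv": outdir / "counts.tsv",
        "conservation_tsv": outdir / "conservation.tsv",
        "term_map_tsv": outdir / "term_map.tsv",
        "truth_features_tsv": outdir / "truth_features.tsv",
        "truth_cis_tsv": outdir / "truth_cis_pairs.tsv",
        "truth_size_factors_tsv": outdir / "truth_size_factors.tsv",
        "config_json": outdir / "config.json",
    }
    write_gtf(reference, paths["reference_gtf"])
    write_gtf(assembled, paths["assembled_gtf"])
    write_fasta(genome.values(), paths["genome_fasta"])
    counts.to_tsv(paths["counts_tsv"])
    conservation.to_csv(paths["conservation_tsv"], sep="\t", header=False, index=False)
    term_map.to_csv(paths["term_map_tsv"], sep="\t", index=False)
    truth.features.to_csv(paths["truth_features_tsv"], sep="\t")
    truth.cis_pairs.to_csv(paths["truth_cis_tsv"], sep="\t", index=False)
    truth.size_factors.to_csv(paths["truth_size_factors_tsv"], sep="\t")
    cfg.to_json(paths["config_json"])
    return paths
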