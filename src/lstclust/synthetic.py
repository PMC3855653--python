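"""Ground-truthed synthetic transcriptomes for exercising the full pipeline.

The generator emulates the failure modes the clustering heuristic targets:
gene families with diverged paralogs, per-gene isoform sets carrying
retained introns and 5'/3' fragments, and noisy initial (assembler) loci
that both over-merge paralogs into one locus and split true loci across
several.  Per-species reference peptides are translations of each gene's
coding sequence after ortholog-level divergence, so annotation transfer,
family-size and single-copy metrics, and intron/UTR recovery can all be
scored against an exact truth table.  Generation is fully determined by
the seed.

Retained introns are GC-poor (mirroring the real contrast between coding
and intronic composition in plants), are inserted at codon boundaries, and
begin and end with in-frame stop codons — the reading-frame disruption
that makes a retained intron visible to a translated search.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score
from Bio.Seq import Seq

from .read_trim import QualityRead, write_fastq
from .seqio import ReferenceProtein, Transcript, revcomp, write_fasta

__all__ = ["SimConfig", "TruthTable", "SimResult", "generate", "generate_reads", "score_vs_truth"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic transcriptome.

    Counts are drawn from geometric distributions (minimum 1) with the
    given means; divergences are per-site substitution probabilities.
    """

    seed: int = 0
    n_families: int = 10
    paralogs_per_family: float = 1.8  # geometric mean
    paralog_divergence: float = 0.2
    n_species: int = 3
    ortholog_divergence: float = 0.05
    isoforms_per_gene: float = 2.0  # geometric mean
    isoform_divergence: float = 0.01  # assembly-variant noise between isoforms
    intron_retention_prob: float = 0.3
    intron_length: tuple[int, int] = (150, 400)
    intron_gc: float = 0.30
    fragment_prob: float = 0.2
    fragment_min_frac: float = 0.5
    overmerge_prob: float = 0.3  # chance a paralog shares its initial locus
    split_prob: float = 0.2  # chance a locus's transcripts are split
    utr_length: tuple[int, int] = (30, 150)
    cds_codons: tuple[int, int] = (120, 250)

    def __post_init__(self) -> None:
        for name in (
            "paralog_divergence",
            "ortholog_divergence",
            "isoform_divergence",
            "intron_retention_prob",
            "fragment_prob",
            "fragment_min_frac",
            "overmerge_prob",
            "split_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_families < 1 or self.n_species < 1:
            raise ValueError("need at least one family and one species")


@dataclass
class TruthTable:
    transcript_to_gene: dict[str, str]
    gene_to_family: dict[str, str]
    gene_to_ortholog: dict[str, dict[str, str]]  # gene -> species -> protein id
    spans: dict[str, dict]  # transcript -> {utr5, utr3, introns}

    def genes(self) -> list[str]:
        return sorted(self.gene_to_family)


@dataclass
class SimResult:
    config: SimConfig
    proteins: dict[str, list[ReferenceProtein]]
    transcripts: list[Transcript]
    truth: TruthTable


def _geometric(rng: np.random.Generator, mean: float) -> int:
    if mean <= 1.0:
        return 1
    return int(rng.geometric(1.0 / mean))


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(rng.choice(_BASES, size=length, p=p)).decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return bytes(arr).decode()


def _sanitize_cds(rng: np.random.Generator, cds: str) -> str:
    """Force ATG start, terminal stop, and no internal stop codons."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    codons[0] = "ATG"
    for i in range(1, len(codons) - 1):
        while codons[i] in _STOPS:
            codons[i] = _random_seq(rng, 3)
    if codons[-1] not in _STOPS:
        codons[-1] = _STOPS[int(rng.integers(len(_STOPS)))]
    return "".join(codons)


def _make_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = _random_seq(rng, 3 * n_codons)
    return _sanitize_cds(rng, body)


def _make_intron(rng: np.random.Generator, cfg: SimConfig) -> str:
    lo, hi = cfg.intron_length
    length = int(rng.integers(lo, hi + 1))
    length = max(9, 3 * (length // 3))  # whole codons, stop-flanked below
    middle = _random_seq(rng, length - 6, cfg.intron_gc)
    first = _STOPS[int(rng.integers(3))]
    last = _STOPS[int(rng.integers(3))]
    return first + middle + last


@dataclass
class _ProtoTranscript:
    gene: str
    sequence: str
    utr5: tuple[int, int]
    utr3: tuple[int, int]
    introns: list[tuple[int, int]]


def _make_isoform(
    rng: np.random.Generator,
    cfg: SimConfig,
    gene: str,
    utr5: str,
    cds: str,
    utr3: str,
    is_primary: bool,
) -> _ProtoTranscript:
    seq = utr5 + cds + utr3
    utr5_span = (0, len(utr5))
    # stop codon is assigned to the 3' UTR: the expected coding length is
    # 3 x protein length, which excludes it
    cds_end = len(utr5) + len(cds) - 3
    utr3_span = (cds_end, len(seq))
    introns: list[tuple[int, int]] = []
    if not is_primary:
        seq = _mutate(rng, seq, cfg.isoform_divergence)
        if rng.random() < cfg.intron_retention_prob:
            intron = _make_intron(rng, cfg)
            n_codons = (len(cds) - 3) // 3
            # codon boundary with a 10-codon margin: flanking exons stay
            # large enough for a translated search to anchor an HSP on
            margin = min(10, n_codons // 3)
            at_codon = int(rng.integers(margin, n_codons - margin + 1))
            pos = len(utr5) + 3 * at_codon
            seq = seq[:pos] + intron + seq[pos:]
            introns.append((pos, pos + len(intron)))
            cds_end += len(intron)
            utr3_span = (cds_end, len(seq))
        if rng.random() < cfg.fragment_prob:
            frac = rng.uniform(cfg.fragment_min_frac, 1.0)
            keep = max(1, int(round(frac * len(seq))))
            if rng.random() < 0.5:
                window = (0, keep)  # 5' fragment
            else:
                window = (len(seq) - keep, len(seq))
            lo, hi = window
            seq = seq[lo:hi]

            def clip(span: tuple[int, int]) -> tuple[int, int]:
                s = min(max(span[0] - lo, 0), hi - lo)
                e = min(max(span[1] - lo, 0), hi - lo)
                return (s, e)

            utr5_span = clip(utr5_span)
            utr3_span = clip(utr3_span)
            introns = [c for c in (clip(i) for i in introns) if c[1] > c[0]]
    return _ProtoTranscript(gene, seq, utr5_span, utr3_span, introns)


def generate(config: SimConfig) -> SimResult:
    """Generate reference proteins, transcripts, noisy initial loci and truth."""
    rng = np.random.default_rng(config.seed)
    proteins: dict[str, list[ReferenceProtein]] = {
        f"sp{s + 1}": [] for s in range(config.n_species)
    }
    gene_to_family: dict[str, str] = {}
    gene_to_ortholog: dict[str, dict[str, str]] = {}
    protos_by_gene: dict[str, list[_ProtoTranscript]] = {}
    family_genes: list[list[str]] = []

    for f in range(config.n_families):
        fam = f"FAM{f + 1:03d}"
        n_codons = int(rng.integers(config.cds_codons[0], config.cds_codons[1] + 1))
        ancestor = _make_cds(rng, n_codons)
        n_paralogs = _geometric(rng, config.paralogs_per_family)
        genes_here: list[str] = []
        for p in range(n_paralogs):
            gene = f"{fam}.g{p + 1}"
            cds = ancestor if p == 0 else _sanitize_cds(
                rng, _mutate(rng, ancestor, config.paralog_divergence)
            )
            utr5 = _random_seq(rng, int(rng.integers(*config.utr_length)), 0.45)
            utr3 = _random_seq(rng, int(rng.integers(*config.utr_length)), 0.45)
            gene_to_family[gene] = fam
            gene_to_ortholog[gene] = {}
            for s in range(config.n_species):
                sp = f"sp{s + 1}"
                ocds = _sanitize_cds(rng, _mutate(rng, cds, config.ortholog_divergence))
                pep = str(Seq(ocds[:-3]).translate())
                pid = f"{sp}_{gene}"
                proteins[sp].append(
                    ReferenceProtein(pid, sp, pep, family_id=fam)
                )
                gene_to_ortholog[gene][sp] = pid
            n_iso = _geometric(rng, config.isoforms_per_gene)
            protos_by_gene[gene] = [
                _make_isoform(rng, config, gene, utr5, cds, utr3, is_primary=(j == 0))
                for j in range(n_iso)
            ]
            genes_here.append(gene)
        family_genes.append(genes_here)

    # --- initial loci: start from true (per-gene) loci, then corrupt ------
    locus_groups: list[list[str]] = []  # lists of gene ids first
    for genes_here in family_genes:
        groups: list[list[str]] = []
        for i, gene in enumerate(genes_here):
            if i > 0 and rng.random() < config.overmerge_prob:
                groups[-1].append(gene)  # over-merge with the previous paralog
            else:
                groups.append([gene])
        locus_groups.extend(groups)

    member_groups: list[list[tuple[str, int]]] = []
    for genes_in_locus in locus_groups:
        members = [
            (gene, j)
            for gene in genes_in_locus
            for j in range(len(protos_by_gene[gene]))
        ]
        if len(members) >= 2 and rng.random() < config.split_prob:
            mask = rng.random(len(members)) < 0.5
            if mask.all() or not mask.any():
                mask[0] = not mask[0]
            part_a = [m for m, keep in zip(members, mask) if keep]
            part_b = [m for m, keep in zip(members, mask) if not keep]
            member_groups.extend([part_a, part_b])
        else:
            member_groups.append(members)

    transcripts: list[Transcript] = []
    transcript_to_gene: dict[str, str] = {}
    spans: dict[str, dict] = {}
    for li, members in enumerate(member_groups, start=1):
        locus = f"Locus_{li}"
        for mi, (gene, j) in enumerate(members, start=1):
            tid = f"{locus}_Transcript_{mi}"
            proto = protos_by_gene[gene][j]
            transcripts.append(Transcript(tid, locus, proto.sequence))
            transcript_to_gene[tid] = gene
            spans[tid] = {
                "utr5": proto.utr5,
                "utr3": proto.utr3,
                "introns": list(proto.introns),
            }
    if not transcripts:
        raise ValueError("configuration generated zero transcripts")
    truth = TruthTable(transcript_to_gene, gene_to_family, gene_to_ortholog, spans)
    return SimResult(config, proteins, transcripts, truth)


def generate_reads(
    transcripts: Sequence[Transcript],
    read_len: int = 90,
    quality_profile: Sequence[int] | None = None,
    n_pairs: int = 1000,
    seed: int = 0,
) -> tuple[list[QualityRead], list[QualityRead]]:
    """Uniform paired fragment sampling with a fixed per-cycle Q profile.

    Base-call errors are substituted at the per-cycle rate implied by the
    profile (p = 10^(-Q/10)).
    """
    min_len = min(t.length for t in transcripts)
    if read_len > min_len:
        raise ValueError("read_len exceeds the shortest transcript")
    if quality_profile is None:
        decay_from = (2 * read_len) // 3
        quality_profile = [
            40 if i < decay_from else max(25, 40 - (i - decay_from)) for i in range(read_len)
        ]
    if len(quality_profile) != read_len:
        raise ValueError("quality profile length must equal read_len")
    rng = np.random.default_rng(seed)
    quals = tuple(int(q) for q in quality_profile)
    perr = np.array([10.0 ** (-q / 10.0) for q in quals])
    reads1, reads2 = [], []
    for i in range(n_pairs):
        t = transcripts[int(rng.integers(len(transcripts)))]
        insert = min(t.length, 2 * read_len)
        start = int(rng.integers(0, t.length - insert + 1))
        frag = t.sequence[start : start + insert]
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])

        def call(seq: str) -> str:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            err = rng.random(len(arr)) < perr
            for k in np.nonzero(err)[0]:
                arr[k] = rng.choice(_BASES[_BASES != arr[k]])
            return bytes(arr).decode()

        name = f"read{i + 1}"
        reads1.append(QualityRead(f"{name}/1", call(r1), quals, 1))
        reads2.append(QualityRead(f"{name}/2", call(r2), quals, 2))
    return reads1, reads2


def score_vs_truth(
    clusters, truth: TruthTable
) -> tuple[float, int, int]:
    """(ARI, split gene count, mixed cluster count) of a partition vs truth.

    ``clusters`` is either a list of objects with ``members`` or a mapping
    transcript id -> cluster label.  Clustered transcripts must be known to
    the truth table; the ARI is computed over the clustered set.
    """
    if isinstance(clusters, Mapping):
        assignment = dict(clusters)
    else:
        assignment = {tid: c.id for c in clusters for tid in c.members}
    unknown = set(assignment) - set(truth.transcript_to_gene)
    if unknown:
        raise ValueError(f"unknown transcript ids: {sorted(unknown)[:3]}...")
    tids = sorted(assignment)
    labels_pred = [assignment[t] for t in tids]
    labels_true = [truth.transcript_to_gene[t] for t in tids]
    ari = float(adjusted_rand_score(labels_true, labels_pred))
    gene_clusters: dict[str, set[str]] = {}
    cluster_genes: dict[str, set[str]] = {}
    for t in tids:
        gene_clusters.setdefault(truth.transcript_to_gene[t], set()).add(assignment[t])
        cluster_genes.setdefault(assignment[t], set()).add(truth.transcript_to_gene[t])
    splits = sum(1 for cs in gene_clusters.values() if len(cs) > 1)
    merges = sum(1 for gs in cluster_genes.values() if len(gs) > 1)
    return ari, splits, merges


def write_simulation(sim: SimResult, outdir: str | Path) -> None:
    """Write all pipeline inputs plus truth tables as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(((t.id, t.sequence) for t in sim.transcripts), outdir / "transcripts.fasta")
    with open(outdir / "locus_map.tsv", "w") as fh:
        for t in sim.transcripts:
            fh.write(f"{t.id}\t{t.initial_locus}\n")
    for sp in sorted(sim.proteins):
        write_fasta(
            ((p.id, p.sequence) for p in sim.proteins[sp]),
            outdir / f"proteins_{sp}.fasta",
        )
        with open(outdir / f"families_{sp}.tsv", "w") as fh:
            for p in sim.proteins[sp]:
                fh.write(f"{p.id}\t{p.family_id}\n")
    with open(outdir / "truth_genes.tsv", "w") as fh:
        for tid in sorted(sim.truth.transcript_to_gene):
            fh.write(f"{tid}\t{sim.truth.transcript_to_gene[tid]}\n")
    with open(outdir / "truth_families.tsv", "w") as fh:
        for g in sorted(sim.truth.gene_to_family):
            fh.write(f"{g}\t{sim.truth.gene_to_family[g]}\n")
    with open(outdir / "truth_spans.json", "w") as fh:
        json.dump(sim.truth.spans, fh, sort_keys=True, indent=0)
        fh.write("\n")
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(asdict(sim.config), fh, sort_keys=True, indent=0)
        fh.write("\n")
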