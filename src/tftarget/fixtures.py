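"""Seeded synthetic annotation + peak generator with known ground truth.

The generator lays lncRNA genes out on toy chromosomes in non-overlapping
slots spaced at least twice the regulatory-window length apart, so every
peak's targeting status is decidable by simple geometry at generation time
— the truth table is computed here, by direct window arithmetic, entirely
independent of the overlap machinery it is used to test.

Datasets come in two flavours:

* *null* datasets draw peak starts uniformly over the genome — what ChIP
  noise with no relationship to the annotation looks like;
* an optional *planted* dataset picks a foreground of genes and drops one
  peak inside the regulatory window of each selected gene (foreground
  members with probability ``hit_fraction_foreground``, background members
  with ``hit_fraction_background``) — a TF that genuinely co-regulates the
  foreground.

All transcripts of a gene share the gene's TSS (alternative 3′ ends), so a
gene has a single window and the truth table stays unambiguous at both the
gene and transcript level.  Everything is driven by one numpy Generator:
the same seed gives byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotations import (
    DEFAULT_WINDOW,
    GeneRecord,
    TranscriptRecord,
    WindowSpec,
)
from .peaks import Peak, PeakDataset

__all__ = ["FixtureError", "PlantedSpec", "FixtureSpec", "Fixture",
           "build_fixture", "generate"]

_JITTER_MAX = 200          # bp of TSS placement noise inside a slot
_TX_LEN_RANGE = (500, 3000)  # synthetic transcript lengths, bp


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of the planted (truly enriched) dataset."""

    dataset_id: str = "DSPLANT"
    tf_name: str = "TF_PLANTED"
    hit_fraction_foreground: float = 0.8
    hit_fraction_background: float = 0.1
    foreground_size: int = 50

    def __post_init__(self) -> None:
        for f in (self.hit_fraction_foreground, self.hit_fraction_background):
            if not 0.0 <= f <= 1.0:
                raise FixtureError(f"hit fractions must be in [0, 1], got {f}")
        if self.foreground_size <= 0:
            raise FixtureError("foreground_size must be positive")


@dataclass(frozen=True)
class FixtureSpec:
    """Everything the generator needs; defaults give a small test genome."""

    seed: int = 0
    n_genes: int = 50
    transcripts_per_gene: tuple[int, int] = (1, 2)
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 3_000_000}
    )
    n_null_datasets: int = 3
    peaks_per_dataset: int = 1_000
    peak_width: int = 200
    window: WindowSpec = DEFAULT_WINDOW
    planted: Optional[PlantedSpec] = None
    cell_line: str = "K562"
    species: str = "Homo sapiens"

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.peaks_per_dataset < 0 or self.peak_width <= 0:
            raise FixtureError("counts must be positive")
        lo, hi = self.transcripts_per_gene
        if not 1 <= lo <= hi:
            raise FixtureError("transcripts_per_gene must be (lo, hi) with 1 <= lo <= hi")
        if self.planted is not None and self.planted.foreground_size > self.n_genes:
            raise FixtureError("foreground_size cannot exceed n_genes")


@dataclass
class Fixture:
    """In-memory fixture: annotation, datasets, and the ground-truth target table."""

    spec: FixtureSpec
    transcripts: list[TranscriptRecord]
    genes: list[GeneRecord]
    datasets: list[PeakDataset]
    #: dataset_id -> gene IDs whose regulatory window the dataset's peaks hit
    truth: dict[str, frozenset]
    #: planted foreground gene IDs (the natural enrichment input); empty if no planting
    foreground: tuple[str, ...]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Generate the fixture in memory (deterministic for a given seed)."""
    rng = np.random.default_rng(spec.seed)
    wlen = spec.window.length
    slot = 2 * wlen + 2 * _JITTER_MAX
    chroms = sorted(spec.chrom_sizes)
    capacity = {c: spec.chrom_sizes[c] // slot for c in chroms}
    if sum(capacity.values()) < spec.n_genes:
        raise FixtureError(
            f"cannot place {spec.n_genes} genes without overlap: capacity is "
            f"{sum(capacity.values())} slots of {slot} bp over {chroms}"
        )

    u, d = spec.window.upstream_bp, spec.window.downstream_bp
    lo_tx, hi_tx = spec.transcripts_per_gene
    transcripts: list[TranscriptRecord] = []
    genes: list[GeneRecord] = []
    # per chrom: parallel lists of window start/end (0-based half-open) and gene index
    win_by_chrom: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chroms}
    gene_windows: list[tuple[str, int, int]] = []  # (chrom, w_start0, w_end0) per gene

    chrom_iter = iter(chroms)
    cur_chrom = next(chrom_iter)
    slot_idx = 0
    for gi in range(spec.n_genes):
        while slot_idx >= capacity[cur_chrom]:
            cur_chrom = next(chrom_iter)
            slot_idx = 0
        base = slot_idx * slot  # 0-based slot origin
        slot_idx += 1

        strand = "+" if rng.random() < 0.5 else "-"
        jitter = int(rng.integers(0, _JITTER_MAX + 1))
        # place the TSS so the whole window sits inside the slot
        if strand == "+":
            tss1 = base + u + 1 + jitter
            w_start0, w_end0 = tss1 - u - 1, tss1 + d
        else:
            tss1 = base + d + 1 + jitter
            w_start0, w_end0 = tss1 - d - 1, tss1 + u

        gene_id = f"GENE{gi:05d}"
        gene_name = f"LNC{gi:05d}"
        n_tx = int(rng.integers(lo_tx, hi_tx + 1))
        tids = []
        for tj in range(n_tx):
            length = int(rng.integers(_TX_LEN_RANGE[0], _TX_LEN_RANGE[1] + 1))
            if strand == "+":
                t_start, t_end = tss1, min(tss1 + length - 1, spec.chrom_sizes[cur_chrom])
            else:
                t_start, t_end = max(1, tss1 - length + 1), tss1
            tid = f"TX{gi:05d}-{tj + 1}"
            tids.append(tid)
            transcripts.append(
                TranscriptRecord(
                    transcript_id=tid,
                    transcript_name=f"{gene_name}-{tj + 1}",
                    gene_id=gene_id,
                    gene_name=gene_name,
                    chrom=cur_chrom,
                    start=t_start,
                    end=t_end,
                    strand=strand,
                    biotype="lincRNA",
                )
            )
        genes.append(GeneRecord(gene_id, gene_name, cur_chrom, strand, tuple(tids)))
        win_by_chrom[cur_chrom].append((w_start0, w_end0, gi))
        gene_windows.append((cur_chrom, w_start0, w_end0))

    win_arrays = {}
    for c in chroms:
        wins = win_by_chrom[c]
        win_arrays[c] = (
            np.array([w[0] for w in wins], dtype=np.int64),
            np.array([w[1] for w in wins], dtype=np.int64),
            np.array([w[2] for w in wins], dtype=np.int64),
        )

    gene_ids = [g.gene_id for g in genes]
    datasets: list[PeakDataset] = []
    truth: dict[str, frozenset] = {}

    sizes = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    pw = spec.peak_width

    for di in range(spec.n_null_datasets):
        ds_id = f"DSNULL{di + 1:03d}"
        counts = rng.multinomial(spec.peaks_per_dataset, probs)
        peaks: list[Peak] = []
        hit_idx: set[int] = set()
        for c, cnt in zip(chroms, counts):
            if cnt == 0:
                continue
            hi = spec.chrom_sizes[c] - pw
            starts = np.sort(rng.integers(0, hi + 1, size=cnt))
            ends = starts + pw
            hit_idx.update(_windows_hit(win_arrays[c], starts, ends))
            peaks.extend(
                Peak(c, int(s), int(s) + pw, f"{ds_id}_pk{k}", 0.0, ".")
                for k, s in enumerate(starts)
            )
        datasets.append(
            PeakDataset(ds_id, f"TF_N{di + 1:03d}", spec.cell_line, spec.species, peaks)
        )
        truth[ds_id] = frozenset(gene_ids[i] for i in hit_idx)

    foreground: tuple[str, ...] = ()
    if spec.planted is not None:
        pl = spec.planted
        fg_idx = np.sort(rng.choice(spec.n_genes, size=pl.foreground_size, replace=False))
        fg_set = set(int(i) for i in fg_idx)
        foreground = tuple(gene_ids[i] for i in fg_idx)
        peaks = []
        hit_genes = []
        for gi in range(spec.n_genes):
            frac = pl.hit_fraction_foreground if gi in fg_set else pl.hit_fraction_background
            if rng.random() >= frac:
                continue
            chrom, w0, w1 = gene_windows[gi]
            width = min(pw, w1 - w0)
            start = int(rng.integers(w0, w1 - width + 1))
            peaks.append(
                Peak(chrom, start, start + width, f"{pl.dataset_id}_pk{len(peaks)}", 0.0, ".")
            )
            hit_genes.append(gene_ids[gi])
        # peak files are conventionally position-sorted; order within the file
        # carries no meaning downstream
        peaks.sort(key=lambda p: (p.chrom, p.start))
        datasets.append(
            PeakDataset(pl.dataset_id, pl.tf_name, spec.cell_line, spec.species, peaks)
        )
        truth[pl.dataset_id] = frozenset(hit_genes)

    return Fixture(spec, transcripts, genes, datasets, truth, foreground)


def _windows_hit(arrays, peak_starts, peak_ends):
    """Gene indexes whose window overlaps any peak (direct geometry, vectorized).

    Windows are sorted and non-overlapping by construction; slots guarantee a
    peak can touch at most the window at or just after its start position,
    but both neighbours are checked anyway.
    """
    ws, we, gidx = arrays
    if len(ws) == 0 or len(peak_starts) == 0:
        return []
    hit = []
    pos = np.searchsorted(ws, peak_starts, side="right") - 1
    for j in (0, 1):
        cand = pos + j
        ok = (cand >= 0) & (cand < len(ws))
        c = cand[ok]
        overlaps = (peak_starts[ok] < we[c]) & (peak_ends[ok] > ws[c])
        hit.append(gidx[c[overlaps]])
    return np.unique(np.concatenate(hit)).tolist()


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def generate(spec: FixtureSpec, out_dir) -> dict[str, str]:
    """Write the fixture as standard files; returns a name -> path map.

    Produces ``annotations.gtf``, one ``<dataset_id>.narrowPeak`` per
    dataset, ``manifest.tsv``, ``truth.tsv`` (dataset_id, feature_id at the
    gene level), and — when a planted dataset is requested — ``input.txt``
    with the foreground gene IDs.  Byte-identical across runs with the same
    spec.
    """
    fx = build_fixture(spec)
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {}

    gtf_path = os.path.join(out_dir, "annotations.gtf")
    by_gene = {g.gene_id: [] for g in fx.genes}
    for t in fx.transcripts:
        by_gene[t.gene_id].append(t)
    with open(gtf_path, "w") as fh:
        for g in fx.genes:
            members = by_gene[g.gene_id]
            g_start = min(t.start for t in members)
            g_end = max(t.end for t in members)
            fh.write(
                f"{g.chrom}\ttftarget\tgene\t{g_start}\t{g_end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}"; gene_type "lincRNA"; gene_name "{g.gene_name}";\n'
            )
            for t in members:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_type "{t.biotype}"; gene_name "{t.gene_name}"; '
                    f'transcript_type "{t.biotype}"; transcript_name "{t.transcript_name}";'
                )
                for feature in ("transcript", "exon"):
                    fh.write(
                        f"{t.chrom}\ttftarget\t{feature}\t{t.start}\t{t.end}\t.\t"
                        f"{t.strand}\t.\t{attrs}\n"
                    )
    paths["gtf"] = gtf_path

    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w") as mh:
        mh.write("path\tdataset_id\ttf\tcell_line\tspecies\tdialect\n")
        for ds in fx.datasets:
            fname = f"{ds.dataset_id}.narrowPeak"
            with open(os.path.join(out_dir, fname), "w") as ph:
                for p in ds.peaks:
                    ph.write(
                        f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t-1\t-1\t-1\t-1\n"
                    )
            mh.write(
                f"{fname}\t{ds.dataset_id}\t{ds.tf_name}\t{ds.cell_line}\t{ds.species}\tnarrowPeak\n"
            )
    paths["manifest"] = manifest_path

    truth_path = os.path.join(out_dir, "truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("dataset_id\tfeature_id\n")
        for ds_id in sorted(fx.truth):
            for fid in sorted(fx.truth[ds_id]):
                fh.write(f"{ds_id}\t{fid}\n")
    paths["truth"] = truth_path

    if fx.foreground:
        input_path = os.path.join(out_dir, "input.txt")
        with open(input_path, "w") as fh:
            for fid in fx.foreground:
                fh.write(fid + "\n")
        paths["input"] = input_path

    return paths
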