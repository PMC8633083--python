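"""Blockwise SFS extraction from phased, ancestral-polarized variant data.

Variants come from a VCF; haplotypes must be phased and every retained site
polarized to an ancestral allele (the ``AA`` INFO tag, else an ancestral
FASTA, else the site is dropped and logged).  Only biallelic SNPs are used.
Coordinates are 1-based inclusive externally (the VCF convention) and
half-open 0-based internally; a variant at the anchor position itself
belongs to no block.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .partition import ParameterError
from .simulate import block_distances

logger = logging.getLogger(__name__)

__all__ = ["BlockGeometry", "BlockExtraction", "extract_blocks"]


@dataclass(frozen=True)
class BlockGeometry:
    """Nonoverlapping blocks of l bases flanking an anchor position.

    ``B`` blocks split evenly left/right, contiguous outward from the
    anchor; block i (1-based, counted outward) spans offsets
    ``(i-1)*l+1 .. i*l`` and has center distance ``i*l - l/2``.  Block
    indices in arrays run from the outermost left block to the outermost
    right block, matching the simulator's layout.
    """

    contig: str
    anchor: int          # 1-based position of the selected site
    l: int
    B: int

    def __post_init__(self):
        if self.l < 1:
            raise ParameterError("block length must be >= 1")
        if self.B < 2 or self.B % 2:
            raise ParameterError("B must be even and >= 2")
        if self.anchor < 1:
            raise ParameterError("anchor is a 1-based coordinate")

    @property
    def distances(self) -> np.ndarray:
        return block_distances(self.B, self.l)

    @property
    def span(self) -> tuple:
        """1-based inclusive (start, end) of the covered region."""
        half = self.B // 2 * self.l
        return max(1, self.anchor - half), self.anchor + half

    def block_of(self, pos: int) -> int | None:
        """Block index of a 1-based position, or None (incl. the anchor)."""
        if pos == self.anchor:
            return None
        off = pos - self.anchor
        i = math.ceil(abs(off) / self.l)
        if i > self.B // 2:
            return None
        if off > 0:
            return self.B // 2 + i - 1
        return self.B // 2 - i


@dataclass
class BlockExtraction:
    """Per-block derived-allele carrier sets plus bookkeeping."""

    geometry: BlockGeometry
    nhap: int
    samples: list
    blocks: list                      # per block: list of carrier frozensets
    dropped: dict = field(default_factory=dict)

    def n_variants(self) -> int:
        return sum(len(b) for b in self.blocks)

    def to_configs(self, x: int = 4, kmax: int = 2) -> np.ndarray:
        from .inference import SampleConfig, tabulate_bsfs

        return tabulate_bsfs(self.blocks, SampleConfig(self.nhap, x), kmax)

    def to_dataset(self, x: int = 4, kmax: int = 2):
        from .simulate import ReplicateDataset

        cfg = self.to_configs(x=x, kmax=kmax)
        return ReplicateDataset(
            distances=self.geometry.distances,
            alphas=np.full(self.geometry.B, np.nan),
            configs=cfg, kmax=kmax, n=self.nhap, x=x, mode="observed",
            provenance={"contig": self.geometry.contig,
                        "anchor": self.geometry.anchor,
                        "l": self.geometry.l, "B": self.geometry.B,
                        "samples": self.samples,
                        "dropped": self.dropped})


def extract_blocks(vcf_path, geometry: BlockGeometry, samples=None,
                   ancestral_fasta=None, allow_unphased: bool = False
                   ) -> BlockExtraction:
    """Extract per-block, per-haplotype derived-allele carrier sets.

    Retains biallelic SNPs with resolvable ancestral state and complete,
    phased genotypes for the requested samples; every exclusion is counted
    in ``dropped``.  If the ancestral allele equals the ALT allele the
    derived indicators are complemented (REF is the derived state).
    """
    import pysam

    fasta = None
    if ancestral_fasta is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(ancestral_fasta))
    lo, hi = geometry.span
    dropped = {"outside": 0, "not_snp": 0, "multiallelic": 0,
               "missing_gt": 0, "unphased": 0, "no_ancestral": 0,
               "aa_mismatch": 0, "monomorphic": 0, "at_anchor": 0}
    with pysam.VariantFile(str(vcf_path)) as vf:
        if samples is None:
            samples = list(vf.header.samples)
        blocks = [[] for _ in range(geometry.B)]
        nhap = 2 * len(samples)
        for rec in vf:
            if rec.contig != geometry.contig or not lo <= rec.pos <= hi:
                dropped["outside"] += 1
                continue
            if rec.pos == geometry.anchor:
                dropped["at_anchor"] += 1
                continue
            bi = geometry.block_of(rec.pos)
            if bi is None:
                dropped["outside"] += 1
                continue
            alts = rec.alts or ()
            if len(alts) != 1:
                dropped["multiallelic" if len(alts) > 1 else "not_snp"] += 1
                continue
            ref, alt = rec.ref.upper(), alts[0].upper()
            if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                dropped["not_snp"] += 1
                continue
            aa = rec.info.get("AA", None)
            if isinstance(aa, (tuple, list)):
                aa = aa[0]
            if aa is not None:
                aa = str(aa).split("|")[0].upper()
            if (aa is None or aa not in "ACGT") and fasta is not None:
                aa = str(fasta[rec.contig][rec.pos - 1]).upper()
            if aa is None or aa not in "ACGT":
                dropped["no_ancestral"] += 1
                continue
            if aa not in (ref, alt):
                dropped["aa_mismatch"] += 1
                continue
            carriers = set()
            ok = True
            hap = 0
            for sname in samples:
                sd = rec.samples[sname]
                gt = sd["GT"]
                if gt is None or any(a is None for a in gt):
                    dropped["missing_gt"] += 1
                    ok = False
                    break
                if len(gt) == 2 and not sd.phased and not allow_unphased:
                    raise ParameterError(
                        f"unphased genotype for sample {sname} at "
                        f"{rec.contig}:{rec.pos}; rerun with "
                        "allow_unphased=True to accept allele order as given")
                for a in gt:
                    derived = (a != 0) if aa == ref else (a == 0)
                    if derived:
                        carriers.add(hap)
                    hap += 1
            if not ok:
                continue
            if not carriers:
                dropped["monomorphic"] += 1
                continue
            blocks[bi].append(frozenset(carriers))
    for key, cnt in dropped.items():
        if cnt:
            logger.info("extract_blocks: dropped %d sites (%s)", cnt, key)
    return BlockExtraction(geometry=geometry, nhap=nhap,
                           samples=list(samples), blocks=blocks,
                           dropped=dropped)
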