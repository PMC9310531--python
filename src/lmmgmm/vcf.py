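"""Optional VCF + BED input for the genomic layer.

Dosages are alternate-allele counts; regions come from a BED file (0-based,
half-open intervals, one region per line with its name in column 4).
Multi-allelic sites are split into one biallelic record per alternate
allele.  Missing genotypes are rejected, not imputed.

Requires ``cyvcf2`` (install the ``vcf`` extra).
"""

from __future__ import annotations

import numpy as np

from .io import DataValidationError


def read_bed_regions(bed_path: str) -> list[tuple[str, int, int, str]]:
    """(chrom, start, end, region_id) per BED line; 0-based half-open."""
    regions: list[tuple[str, int, int, str]] = []
    with open(bed_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataValidationError(
                    f"{bed_path}:{ln}: need 4 columns (chrom, start, end, name)"
                )
            regions.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    if not regions:
        raise DataValidationError(f"{bed_path}: no regions")
    return regions


def read_genotypes_vcf(
    vcf_path: str, bed_path: str
) -> tuple[list[str], dict[str, np.ndarray], list[tuple[str, str, str]]]:
    """Read per-region dosage blocks from a VCF.

    Returns ``(sample_ids, G_blocks, region_map_entries)`` ready to assemble
    into an :class:`~lmmgmm.io.OmicsDataset` (entries have layer "genomic").
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "VCF input requires cyvcf2; install the 'vcf' extra"
        ) from exc

    regions = read_bed_regions(bed_path)
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    blocks: dict[str, list[np.ndarray]] = {name: [] for *_, name in regions}
    feature_names: dict[str, list[str]] = {name: [] for *_, name in regions}

    for variant in vcf:
        hits = [
            name
            for chrom, start, end, name in regions
            if variant.CHROM == chrom and start <= variant.start < end
        ]
        if not hits:
            continue
        gts = np.asarray(variant.genotype.array())[:, :2]
        if (gts < 0).any():
            bad = [samples[i] for i in np.flatnonzero((gts < 0).any(axis=1))]
            raise DataValidationError(
                f"missing genotype at {variant.CHROM}:{variant.POS} "
                f"for samples {bad[:10]}; imputation is not performed"
            )
        # split multi-allelic sites into one biallelic dosage per ALT allele
        for alt_idx, alt in enumerate(variant.ALT, start=1):
            dosage = (gts == alt_idx).sum(axis=1).astype(float)
            feat = f"{variant.CHROM}:{variant.POS}:{variant.REF}:{alt}"
            for name in hits:
                blocks[name].append(dosage)
                feature_names[name].append(feat)

    G_blocks = {
        name: np.column_stack(cols) for name, cols in blocks.items() if cols
    }
    if not G_blocks:
        raise DataValidationError("no VCF variants fall inside the BED regions")
    entries = [
        (feat, "genomic", name)
        for name in G_blocks
        for feat in feature_names[name]
    ]
    return samples, G_blocks, entries
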