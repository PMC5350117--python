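"""Readers and writers for the standard interchange formats.

VCF parsing goes through cyvcf2; written VCFs are plain-text v4.2 (the
simulator's callsets are small and uncompressed text keeps artifacts
diff-able).  Targets and SegDups travel as BED (0-based half-open; columns
chrom, start, end, gene, exon_index / validated flag), per-base depth as a
3-column TSV (chrom, 1-based pos, depth; gzip accepted via suffix), and
confirmations / replicate manifests / variant annotation tables as TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .concordance import CallSet, GenotypeClass, VariantKey, left_trim
from .confirmation import ConfirmationRecord
from .coverage import DepthTrack
from .regions import RegionIndex, SegDupRegion, TargetRegion
from .triage import AnnotatedVariant
from .variability import ReplicateLabel

_GT_TO_VCF = {GenotypeClass.HOM_REF: "0/0", GenotypeClass.HET: "0/1",
              GenotypeClass.HOM_ALT: "1/1", GenotypeClass.MISSING: "./."}


# ---------------------------------------------------------------- VCF

def write_vcf(callset: CallSet, path: str | Path) -> None:
    """Write a single-sample VCF v4.2 with GT-only records, sorted."""
    path = Path(path)
    contigs = sorted({k.chrom for k in callset.calls})
    lines = (["##fileformat=VCFv4.2"]
             + [f"##contig=<ID={c}>" for c in contigs]
             + ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + callset.sample_id])
    for key in sorted(callset.calls):
        gt = _GT_TO_VCF[callset.calls[key]]
        lines.append(f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}"
                     f"\t.\t.\t.\tGT\t{gt}")
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path, sample: str | None = None,
             assessed_regions: RegionIndex | None = None) -> CallSet:
    """Read one sample's calls from a VCF into a CallSet.

    Multi-allelic records are decomposed into biallelic keys (an alt allele
    counted twice in the genotype is hom-alt, once is het, zero hom-ref);
    alleles are left-trimmed.  `sample` selects the column of a multi-sample
    file (default: the single/first sample).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"no sample columns in {path}")
    if sample is None:
        sample_idx = 0
        sample = samples[0]
    else:
        if sample not in samples:
            raise KeyError(f"sample {sample!r} not in {path}")
        sample_idx = samples.index(sample)
    calls: dict[VariantKey, GenotypeClass] = {}
    for record in vcf:
        genotype = record.genotypes[sample_idx]
        alleles = [a for a in genotype[:-1]]
        for alt_index, alt in enumerate(record.ALT, start=1):
            if alt in (".", "*", None):
                continue
            if any(a == -1 for a in alleles):
                gt = GenotypeClass.MISSING
            else:
                n_alt = sum(a == alt_index for a in alleles)
                gt = (GenotypeClass.HOM_ALT if n_alt == len(alleles)
                      else GenotypeClass.HET if n_alt >= 1
                      else GenotypeClass.HOM_REF)
            key = left_trim(record.CHROM, record.POS, record.REF, alt)
            if gt is not GenotypeClass.HOM_REF:
                calls[key] = gt
    vcf.close()
    return CallSet(sample_id=sample, calls=calls,
                   assessed_regions=assessed_regions or RegionIndex())


# ---------------------------------------------------------------- BED

def write_targets_bed(targets: list[TargetRegion], path: str | Path) -> None:
    rows = [f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene}\t{t.exon_index}"
            for t in sorted(targets)]
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_targets_bed(path: str | Path) -> list[TargetRegion]:
    targets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        gene = fields[3] if len(fields) > 3 else ""
        exon = int(fields[4]) if len(fields) > 4 else 0
        targets.append(TargetRegion(chrom, start, end, gene, exon))
    return targets


def write_segdups_bed(segdups: list[SegDupRegion], path: str | Path) -> None:
    rows = [f"{s.chrom}\t{s.start}\t{s.end}\tsegdup\t"
            f"{int(s.validated_unambiguous)}"
            for s in sorted(segdups, key=lambda s: (s.chrom, s.start))]
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_segdups_bed(path: str | Path) -> list[SegDupRegion]:
    segdups = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        validated = bool(int(fields[4])) if len(fields) > 4 else False
        segdups.append(SegDupRegion(fields[0], int(fields[1]),
                                    int(fields[2]), validated))
    return segdups


# ---------------------------------------------------------------- depth TSV

def write_depth_tsv(track: DepthTrack, path: str | Path) -> None:
    df = pd.DataFrame(track.records(), columns=["chrom", "pos", "depth"])
    df.to_csv(path, sep="\t", index=False)


def read_depth_tsv(path: str | Path) -> DepthTrack:
    df = pd.read_csv(path, sep="\t")
    expected = {"chrom", "pos", "depth"}
    if not expected.issubset(df.columns):
        # headerless 3-column variant
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "pos", "depth"])
    return DepthTrack.from_records(
        df[["chrom", "pos", "depth"]].itertuples(index=False, name=None))


# ---------------------------------------------------------------- TSV tables

def write_confirmations_tsv(records: list[ConfirmationRecord],
                            path: str | Path) -> None:
    rows = [{"chrom": r.key.chrom, "pos": r.key.pos, "ref": r.key.ref,
             "alt": r.key.alt, "outcome": r.outcome, "method": r.method}
            for r in records]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "outcome",
                                "method"]).to_csv(path, sep="\t", index=False)


def read_confirmations_tsv(path: str | Path) -> list[ConfirmationRecord]:
    df = pd.read_csv(path, sep="\t")
    return [ConfirmationRecord(
                key=VariantKey(str(row.chrom), int(row.pos), str(row.ref),
                               str(row.alt)),
                outcome=str(row.outcome), method=str(row.method))
            for row in df.itertuples(index=False)]


def write_replicate_manifest(replicates, directory: str | Path,
                             path: str | Path) -> list[Path]:
    """Write each replicate's VCF plus the manifest TSV pointing at them."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows, paths = [], []
    for label, callset in replicates:
        vcf_path = directory / f"{callset.sample_id}.vcf"
        write_vcf(callset, vcf_path)
        paths.append(vcf_path)
        rows.append({"sample_id": label.sample_id, "run_id": label.run_id,
                     "operator": label.operator, "lot": label.reagent_lot,
                     "day": label.day, "plex": label.plex,
                     "vcf_path": str(vcf_path)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return paths


def read_replicate_manifest(path: str | Path,
                            assessed_regions: RegionIndex | None = None,
                            ) -> list[tuple[ReplicateLabel, CallSet]]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        label = ReplicateLabel(sample_id=str(row.sample_id),
                               run_id=str(row.run_id),
                               operator=str(row.operator),
                               reagent_lot=str(row.lot), day=str(row.day),
                               plex=int(row.plex))
        vcf_path = Path(str(row.vcf_path))
        if not vcf_path.exists():
            raise FileNotFoundError(
                f"replicate {row.sample_id}/{row.run_id}: missing VCF "
                f"{vcf_path}")
        callset = read_vcf(vcf_path, assessed_regions=assessed_regions)
        out.append((label, callset))
    return out


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, str) and value.upper() in
                         ("NA", "", ".")) or pd.isna(value):
        return None
    return float(value)


def read_variant_table(path: str | Path) -> list[AnnotatedVariant]:
    """Annotated variant report TSV -> AnnotatedVariant list.

    Required columns: chrom, pos, ref, alt, gene, consequence, db_presence;
    optional: af_1000g, af_esp6500, in_segdup, segdup_validated, and one
    column per in-silico tool (SIFT, PolyPhen, ...).
    """
    df = pd.read_csv(path, sep="\t")
    known = {"chrom", "pos", "ref", "alt", "gene", "consequence",
             "db_presence", "af_1000g", "af_esp6500", "in_segdup",
             "segdup_validated"}
    tool_cols = [c for c in df.columns if c not in known]
    variants = []
    # dict records, not itertuples: tool names like GERP++ are not
    # valid identifiers and would be mangled
    for d in df.to_dict(orient="records"):
        variants.append(AnnotatedVariant(
            key=VariantKey(str(d["chrom"]), int(d["pos"]), str(d["ref"]),
                           str(d["alt"])),
            gene=str(d["gene"]),
            consequence=str(d.get("consequence", "non_synonymous")),
            db_presence=bool(d.get("db_presence", False)),
            af_1000g=_opt_float(d.get("af_1000g")),
            af_esp6500=_opt_float(d.get("af_esp6500")),
            insilico_scores={c: d[c] for c in tool_cols if not pd.isna(d[c])},
            in_segdup=bool(d.get("in_segdup", False)),
            segdup_validated=bool(d.get("segdup_validated", False)),
        ))
    return variants
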