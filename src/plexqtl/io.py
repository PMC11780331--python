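"""Standard-format I/O: multi-sample VCF in, TSV/BED/manifest out.

The analysis is depth-based: per-sample allele depths come from the VCF
``AD`` FORMAT field and genotype calls in the file are ignored.  Depth
tables are plain pandas DataFrames with ``{role}_ref`` / ``{role}_alt``
columns for the four roles P1, P2, Bulk1, Bulk2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import pandas as pd
import pysam

from . import __version__
from .core import QtlseqResult

ROLES = ("P1", "P2", "Bulk1", "Bulk2")


@dataclass(frozen=True)
class SampleRoleMap:
    """VCF sample name -> analysis role (P1, P2, Bulk1, Bulk2)."""

    p1: str = "P1"
    p2: str = "P2"
    bulk1: str = "Bulk1"
    bulk2: str = "Bulk2"

    def __post_init__(self) -> None:
        if len({self.p1, self.p2, self.bulk1, self.bulk2}) != 4:
            raise ValueError("the four roles must map to distinct samples")

    @property
    def by_role(self) -> dict[str, str]:
        return {"P1": self.p1, "P2": self.p2, "Bulk1": self.bulk1, "Bulk2": self.bulk2}


def read_variant_table(
    path: str,
    roles: SampleRoleMap | None = None,
    max_indel_len: int = 70,
) -> pd.DataFrame:
    """Read biallelic variant observations from a multi-sample VCF.

    Keeps biallelic SNPs and In/Dels shorter than ``max_indel_len`` bp
    (length = |len(ALT) - len(REF)|); multi-allelic records are skipped.
    Depths come from the AD field.  Returns a DataFrame with chrom, pos,
    ref, alt and ``{role}_ref`` / ``{role}_alt`` columns.
    """
    roles = roles or SampleRoleMap()
    rows = []
    with pysam.VariantFile(path) as vcf:
        header_samples = list(vcf.header.samples)
        for role, sample in roles.by_role.items():
            if sample not in header_samples:
                raise ValueError(f"sample {sample!r} (role {role}) absent from VCF header")
        if "AD" not in vcf.header.formats:
            raise ValueError("VCF lacks the AD (allele depth) FORMAT field")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if abs(len(alt) - len(ref)) >= max_indel_len:
                continue
            row = {"chrom": rec.chrom, "pos": rec.pos, "ref": ref, "alt": alt}
            for role, sample in roles.by_role.items():
                ad = rec.samples[sample].get("AD")
                if ad is None or ad[0] is None:
                    raise ValueError(f"missing AD for sample {sample!r} at {rec.chrom}:{rec.pos}")
                row[f"{role.lower()}_ref"] = int(ad[0])
                row[f"{role.lower()}_alt"] = int(ad[1])
            rows.append(row)
    columns = ["chrom", "pos", "ref", "alt"] + [
        f"{r.lower()}_{a}" for r in ROLES for a in ("ref", "alt")
    ]
    return pd.DataFrame(rows, columns=columns)


def write_simulated_vcf(
    observations: pd.DataFrame,
    path: str,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Write a depth table as a minimal VCF 4.2 with AD/DP per sample.

    Samples are named P1, P2, Bulk1, Bulk2.  Records are emitted sorted by
    (chromosome, position); the table round-trips losslessly through
    :func:`read_variant_table`.
    """
    if chrom_lengths is None:
        chrom_lengths = (
            observations.groupby("chrom")["pos"].max().astype(int).to_dict()
            if len(observations)
            else {}
        )
    header = pysam.VariantHeader()
    header.add_line('##source=plexqtl-simulator')
    for chrom in sorted(chrom_lengths):
        header.contigs.add(chrom, length=int(chrom_lengths[chrom]))
    header.formats.add("AD", "R", "Integer", "Allelic depths (REF, ALT)")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    for role in ROLES:
        header.add_sample(role)
    obs = observations.sort_values(["chrom", "pos"], kind="stable") if len(observations) else observations
    with pysam.VariantFile(path, "w", header=header) as out:
        for _, row in obs.iterrows():
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            for role in ROLES:
                key = role.lower()
                ref_d, alt_d = int(row[f"{key}_ref"]), int(row[f"{key}_alt"])
                rec.samples[role]["AD"] = (ref_d, alt_d)
                rec.samples[role]["DP"] = ref_d + alt_d
            out.write(rec)


@dataclass
class RunConfig:
    """All pipeline parameters, serializable as a flat key=value file.

    ``min_mq`` / ``adjust_mq`` are read-alignment/calling-stage settings
    recorded only as pass-through metadata for the run manifest; variant
    calling itself is upstream of this package.
    """

    ploidy: int = 4
    nplex: int = 1
    p2_index_low: float | None = None
    p2_index_high: float | None = None
    min_depth: int = 40
    p1_max_index: float = 0.02
    p1_max_alt_reads: int = 1
    max_indel_len: int = 70
    window_size: int = 100_000
    step: int = 20_000
    count_threshold: int = 100
    replicates: int = 10_000
    n1: int = 18
    n2: int = 18
    seed: int = 0
    min_mq: int = 40
    adjust_mq: int = 60

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                fh.write(f"{key}={'' if value is None else value}\n")

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                if key not in cls.__dataclass_fields__:
                    raise ValueError(f"unknown config key {key!r}")
                if raw == "":
                    kwargs[key] = None
                elif "float" in str(types[key]):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = int(raw)
        return cls(**kwargs)

    @property
    def p2_index_range(self) -> tuple[float, float] | None:
        if self.p2_index_low is None or self.p2_index_high is None:
            return None
        return (self.p2_index_low, self.p2_index_high)


def write_outputs(result: QtlseqResult, outdir, config: RunConfig | None = None) -> dict[str, str]:
    """Write variant/window/region tables and a run manifest.

    Produces ``variants.tsv``, ``windows.tsv``, ``regions.tsv``,
    ``regions.bed`` (0-based half-open) and ``manifest.json`` under
    ``outdir``; all deterministic given the same inputs.  Returns the
    written paths keyed by kind.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    var_cols = [
        "chrom", "pos", "ref", "alt",
        "p1_index", "p2_index", "bulk1_index", "bulk2_index",
        "delta_index", "p_value", "significance", "direction",
    ]
    variants = result.variants
    var_out = variants[[c for c in var_cols if c in variants.columns]]
    paths["variants"] = str(outdir / "variants.tsv")
    var_out.to_csv(paths["variants"], sep="\t", index=False, float_format="%.6g")

    paths["windows"] = str(outdir / "windows.tsv")
    result.windows.to_csv(paths["windows"], sep="\t", index=False, float_format="%.6g")

    paths["regions"] = str(outdir / "regions.tsv")
    result.regions.to_csv(paths["regions"], sep="\t", index=False, float_format="%.6g")

    paths["regions_bed"] = str(outdir / "regions.bed")
    with open(paths["regions_bed"], "w") as bed:
        bed.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for _, r in result.regions.iterrows():
            strand = "+" if r["direction"] == "positive" else "-"
            name = f"qtl_{result.donor}_nplex{result.plexity}"
            bed.write(
                f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t{name}\t"
                f"{int(r['peak_p99_count'])}\t{strand}\n"
            )

    manifest = {
        "package": "plexqtl",
        "version": __version__,
        "donor": result.donor,
        "plexity": result.plexity,
        "n_variants_analyzed": int(len(result.variants)),
        "n_windows": int(len(result.windows)),
        "n_candidate_regions": int(len(result.regions)),
        "config": asdict(config) if config is not None else None,
    }
    paths["manifest"] = str(outdir / "manifest.json")
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
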