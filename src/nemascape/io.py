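"""File formats and reproducibility plumbing.

Coordinate conventions: internal coordinates are 0-based half-open; VCF
positions are written 1-based; BED intervals are 0-based half-open.  All
conversions happen here and nowhere else.  Statistics tables are tidy TSV
with missing values encoded as "NA".
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .landscape import DomainBoundaries, MareyMap

__all__ = [
    "CoverageMask",
    "write_sample_vcf",
    "read_vcf",
    "apply_window_coverage_filter",
    "read_marey_map",
    "write_marey_map",
    "write_domain_report",
    "write_stats_table",
    "read_stats_table",
    "simulation_config_from_toml",
    "write_manifest",
]


# ---------------------------------------------------------------------------
# coverage masks (BED)
# ---------------------------------------------------------------------------


@dataclass
class CoverageMask:
    """Usable-region intervals for one chromosome (0-based, half-open).

    Intervals are sorted and merged on construction, mirroring what
    ``bedtools merge`` produces from combined mask files.
    """

    intervals: np.ndarray  # (n, 2) int64

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if iv.size and np.any(iv[:, 1] < iv[:, 0]):
            raise ValueError("interval end before start")
        if iv.shape[0] > 1:
            iv = iv[np.argsort(iv[:, 0], kind="stable")]
            merged = [iv[0]]
            for s, e in iv[1:]:
                if s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            iv = np.asarray(merged, dtype=np.int64)
        self.intervals = iv

    @classmethod
    def from_bed(cls, path, chrom: str | None = None) -> "CoverageMask":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if chrom is not None and parts[0] != chrom:
                    continue
                rows.append((int(parts[1]), int(parts[2])))
        return cls(np.asarray(rows, dtype=np.int64).reshape(-1, 2))

    def to_bed(self, path, chrom: str = "chr1") -> None:
        with open(path, "w") as fh:
            for s, e in self.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\n")

    def covered_bases(self, start: int, stop: int) -> int:
        if self.intervals.size == 0 or stop <= start:
            return 0
        s = np.maximum(self.intervals[:, 0], start)
        e = np.minimum(self.intervals[:, 1], stop)
        return int(np.clip(e - s, 0, None).sum())

    def coverage_fraction(self, start: int, stop: int) -> float:
        if stop <= start:
            return 0.0
        return self.covered_bases(start, stop) / (stop - start)


def apply_window_coverage_filter(
    table: pd.DataFrame, mask: CoverageMask, threshold: float = 0.1
) -> pd.DataFrame:
    """Drop windows whose usable fraction falls below ``threshold``.

    The conventional cut is 10% for all-site windows and 5% for
    exon/intron-restricted ones.  Surviving windows get their fraction
    recorded in ``coverage_fraction``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    frac = np.array(
        [
            mask.coverage_fraction(int(s), int(e))
            for s, e in zip(table["start"], table["end"])
        ]
    )
    out = table.copy()
    out["coverage_fraction"] = frac
    return out[frac >= threshold].reset_index(drop=True)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_sample_vcf(
    gm: GenotypeMatrix,
    path,
    chrom: str = "1",
    sample_prefix: str = "ind",
    meta: dict | None = None,
) -> None:
    """Write a genotype matrix as VCFv4.2 (biallelic A/T records).

    Simulated variants carry no nucleotide identity, so REF/ALT are written
    as A/T placeholders; GT is phased (``|``) when haplotypes are known,
    unphased (``/``) otherwise.  Positions convert to 1-based.
    """
    n = gm.n_individuals
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    length = gm.sequence_length
    if length is None:
        length = int(gm.positions[-1]) + 1 if gm.n_sites else 1
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for key, val in (meta or {}).items():
        lines.append(f"##{key}={val}")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    phased = gm.phased
    sep = "|" if phased else "/"
    for i in range(gm.n_sites):
        if phased:
            h = gm.haplotypes[i]
            gts = [f"{h[2 * j]}{sep}{h[2 * j + 1]}" for j in range(n)]
        else:
            d = gm.dosages[i]
            lut = {0: "0/0", 1: "0/1", 2: "1/1"}
            gts = [lut[int(x)] for x in d]
        lines.append(
            f"{chrom}\t{int(gm.positions[i]) + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, chrom: str | None = None) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF into a genotype matrix (cyvcf2).

    Multiallelic records are skipped; phase is retained when every
    genotype in the file is phased.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    positions, haps, doses = [], [], []
    all_phased = True
    length = None
    for rec in vcf:
        if chrom is not None and rec.CHROM != chrom:
            continue
        if len(rec.ALT) != 1:
            continue
        g = np.asarray(rec.genotypes, dtype=np.int64)  # (n, 3): a0 a1 phased
        if np.any(g[:, :2] < 0):
            continue  # drop sites with missing calls
        positions.append(rec.POS - 1)
        haps.append(g[:, :2].reshape(-1))
        doses.append(g[:, 0] + g[:, 1])
        all_phased = all_phased and bool(np.all(g[:, 2] == 1))
    for contig in vcf.seqlens or []:
        length = int(contig)
        break
    vcf.close()
    if not positions:
        return GenotypeMatrix(
            positions=np.zeros(0, dtype=np.int64),
            dosages=np.zeros((0, 0), dtype=np.int8),
            sequence_length=length,
        )
    pos = np.asarray(positions, dtype=np.int64)
    order = np.argsort(pos, kind="stable")
    hap_mat = np.asarray(haps, dtype=np.int8)[order]
    dose_mat = np.asarray(doses, dtype=np.int8)[order]
    if all_phased:
        return GenotypeMatrix.from_haplotypes(pos[order], hap_mat, length)
    return GenotypeMatrix(
        positions=pos[order], dosages=dose_mat, sequence_length=length
    )


# ---------------------------------------------------------------------------
# Marey maps and domain reports (TSV)
# ---------------------------------------------------------------------------


def read_marey_map(path, chrom: str | None = None, kind: str = "sex-averaged") -> MareyMap:
    """Read a 3-column TSV (chrom, pos_bp, cM) as a Marey map."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    if chrom is not None:
        df = df[df["chrom"].astype(str) == str(chrom)]
    return MareyMap(
        physical_pos=df["pos_bp"].to_numpy(float),
        genetic_pos=df["cm"].to_numpy(float),
        chrom="" if chrom is None else str(chrom),
        kind=kind,
    )


def write_marey_map(marey: MareyMap, path, chrom: str | None = None) -> None:
    pd.DataFrame(
        {
            "chrom": chrom or marey.chrom or "chr1",
            "pos_bp": marey.physical_pos.astype(np.int64),
            "cM": marey.genetic_pos,
        }
    ).to_csv(path, sep="\t", index=False)


def write_domain_report(
    boundaries: list[DomainBoundaries], chrom_sizes: list[int], path
) -> None:
    """Boundary report in the conventional layout: per chromosome the
    central-domain edges in kb with 95% CIs, per-domain rates in cM/Mb and
    the chromosome size (boundaries reported 1-based inclusive)."""
    rows = []
    for b, size in zip(boundaries, chrom_sizes):
        (lo1, hi1), (lo2, hi2) = b.boundary_CIs
        rows.append(
            dict(
                chrom=b.chrom,
                left_arm_end_kb=round(b.left_arm_end / 1e3),
                left_CI_kb=f"{round(lo1 / 1e3)}-{round(hi1 / 1e3)}",
                right_arm_start_kb=round(b.right_arm_start / 1e3),
                right_CI_kb=f"{round(lo2 / 1e3)}-{round(hi2 / 1e3)}",
                rate_left_cM_Mb=round(b.domain_slopes[0], 3),
                rate_center_cM_Mb=round(b.domain_slopes[1], 3),
                rate_right_cM_Mb=round(b.domain_slopes[2], 3),
                chrom_size_bp=int(size),
                degenerate=b.degenerate,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_stats_table(table: pd.DataFrame, path) -> None:
    """Tidy one-row-per-window TSV; missing values written as NA."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_stats_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


# ---------------------------------------------------------------------------
# TOML configuration and manifests
# ---------------------------------------------------------------------------


def simulation_config_from_toml(path):
    """Build a :class:`~nemascape.simulate.SimulationConfig` from TOML.

    Layout::

        [population]
        N = 500
        selfing_rate = 0.98        # or [[generation, rate], ...]
        generations = 0
        burn_in = 5000             # optional, defaults to 10 N
        sample_size = 50
        seed = 1

        [chromosome]
        arm_len = 100000
        center_len = 100000
        arm_rec = 2.5e-6
        center_rec = 1e-8
        base_mut = 2e-7
        mut_multipliers = [1.0, 1.0, 1.0]

        [dfe]
        class_fractions = [0.9, 0.1, 0.0, 0.0]
        # optional: del_gamma, ben_gamma, bal_s, balancing_mode
    """
    import tomllib

    from .landscape import build_chromosome_model
    from .simulate import DFEConfig, SimulationConfig

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    c = doc["chromosome"]
    model = build_chromosome_model(
        c["arm_len"],
        c["center_len"],
        c["arm_rec"],
        c["center_rec"],
        c["base_mut"],
        tuple(c.get("mut_multipliers", (1.0, 1.0, 1.0))),
    )
    d = doc.get("dfe", {})
    dfe_kwargs = {}
    if "class_fractions" in d:
        dfe_kwargs["class_fractions"] = tuple(d["class_fractions"])
    for key in ("del_gamma", "ben_gamma"):
        if key in d:
            dfe_kwargs[key] = tuple(d[key])
    for key in ("bal_s", "balancing_mode"):
        if key in d:
            dfe_kwargs[key] = d[key]
    p = doc["population"]
    selfing = p.get("selfing_rate", 0.0)
    if isinstance(selfing, list):
        selfing = [(int(g), float(r)) for g, r in selfing]
    return SimulationConfig(
        N=int(p["N"]),
        model=model,
        selfing_rate=selfing,
        dfe=DFEConfig(**dfe_kwargs),
        generations=int(p.get("generations", 0)),
        burn_in=p.get("burn_in"),
        sample_size=int(p.get("sample_size", 100)),
        seed=p.get("seed"),
        demography=[(int(g), int(n)) for g, n in p.get("demography", [])] or None,
    )


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed=None, inputs=()) -> dict:
    """Emit a reproducibility manifest: config, seed, package version,
    python version and sha256 of every input file."""
    try:
        version = metadata.version("nemascape")
    except metadata.PackageNotFoundError:
        version = "unknown"
    manifest = {
        "package": "nemascape",
        "version": version,
        "python": sys.version.split()[0],
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": config,
        "inputs": {str(p): _file_sha256(p) for p in inputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
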