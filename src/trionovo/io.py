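"""Readers and writers for the pipeline's on-disk formats.

Coordinates are 0-based half-open everywhere in memory; only VCF records
use 1-based positions, converted at the read/write boundary.  The VCF
writer emits a custom FORMAT field ``SD`` with four integers
(RF, RR, AF, AR): the standard AD field is strand-collapsed and cannot
carry the strand-resolved allele depths the bias filter needs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import pysam

from .intervals import RegionSet
from .simulate import DepthTrack, GT_MISSING

SAMPLES = ("father", "mother", "offspring")

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", GT_MISSING: "./."}
_GT_CODE = {(0, 0): 0, (0, 1): 1, (1, 1): 2}


class VcfParseError(ValueError):
    pass


def write_vcf(trio_table: pd.DataFrame, path, chrom_lengths: Dict[str, int],
              samples: Tuple[str, str, str] = SAMPLES) -> None:
    """Write trio genotypes with strand-resolved allele depths.

    Expects chrom, pos (0-based), ref, alt and per-sample columns
    ``gt_<s>``, ``depth_<s>``, ``rf_<s>``, ``rr_<s>``, ``af_<s>``,
    ``ar_<s>``.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=trionovo\n")
        for chrom, ln in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=SD,Number=4,Type=Integer,Description='
                 '"Strand-resolved allele depths: RF,RR,AF,AR">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        df = trio_table.sort_values(["chrom", "pos"])
        for row in df.itertuples():
            fields = [row.chrom, str(int(row.pos) + 1), ".", row.ref, row.alt,
                      ".", "PASS", ".", "GT:DP:SD"]
            for s in samples:
                gt = _GT_STR[int(getattr(row, f"gt_{s}"))]
                dp = int(getattr(row, f"depth_{s}"))
                sd = ",".join(str(int(getattr(row, f"{c}_{s}")))
                              for c in ("rf", "rr", "af", "ar"))
                fields.append(f"{gt}:{dp}:{sd}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path, samples: Tuple[str, str, str] = SAMPLES
             ) -> Tuple[pd.DataFrame, int]:
    """Read a trio VCF into a table; returns (table, n_multiallelic_skipped).

    Positions convert to 0-based; multi-allelic records are skipped and
    counted.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse {path}: {exc}") from exc
    file_samples = list(vcf.header.samples)
    for s in samples:
        if s not in file_samples:
            raise VcfParseError(f"sample {s!r} missing from {path}")
    rows = []
    n_skipped = 0
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        row = {"chrom": rec.chrom, "pos": rec.pos - 1, "ref": rec.ref,
               "alt": alts[0]}
        for s in samples:
            call = rec.samples[s]
            alleles = call.get("GT")
            if alleles is None or None in alleles:
                row[f"gt_{s}"] = GT_MISSING
            else:
                row[f"gt_{s}"] = _GT_CODE[tuple(sorted(alleles))]
            row[f"depth_{s}"] = call.get("DP") or 0
            sd = call.get("SD") or (0, 0, 0, 0)
            for name, v in zip(("rf", "rr", "af", "ar"), sd):
                row[f"{name}_{s}"] = int(v)
        rows.append(row)
    return pd.DataFrame(rows), n_skipped


# -- BED ---------------------------------------------------------------------

def write_bed(regions: RegionSet, path) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path) -> RegionSet:
    """Read BED3 (0-based half-open); overlapping intervals merge on load."""
    ivs = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise VcfParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: interval end <= start")
            ivs.append((chrom, start, end))
    return RegionSet(ivs)


# -- depth tracks (run-length-encoded TSV) -----------------------------------

def write_depth_tsv(track: DepthTrack, path) -> None:
    """Run-length-encoded 4-column depth track: chrom, start, end, depth."""
    with Path(path).open("w") as fh:
        fh.write("chrom\tstart\tend\tdepth\n")
        for chrom in sorted(track.depth):
            arr = track.depth[chrom]
            if not len(arr):
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]}\n")


def read_depth_tsv(path) -> DepthTrack:
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end", "depth"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: interval end <= start")
    depth: Dict[str, np.ndarray] = {}
    for chrom, sub in df.groupby("chrom"):
        sub = sub.sort_values("start")
        L = int(sub["end"].max())
        arr = np.zeros(L, dtype=np.int32)
        for s, e, d in zip(sub["start"], sub["end"], sub["depth"]):
            arr[s:e] = d
        depth[chrom] = arr
    # forward-strand counts are not representable in the RLE track; a
    # re-read track carries an even split for bookkeeping only
    fwd = {c: (a // 2).astype(np.int32) for c, a in depth.items()}
    return DepthTrack(depth, fwd)


# -- generic tables / JSON ---------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
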