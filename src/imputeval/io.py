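"""VCF input/output for genotype panels.

Reading goes through cyvcf2 (htslib); writing emits uncompressed VCF 4.2
text directly so that ``read(write(m))`` reproduces a panel exactly —
dosages, missing calls and the marker map. Only the GT field is required;
GP (genotype posterior probabilities) is written/read when a posterior
tensor is supplied, for info-score computation.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, GenotypeMatrix, MarkerMap


def read_genotypes(
    path: str | os.PathLike,
    field: str = "GT",
    strict: bool = True,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` of ALT dosages.

    Parameters
    ----------
    path : str
        VCF file (plain or bgzipped).
    field : {"GT", "DS"}
        ``GT`` maps diploid hard calls to ALT dosage; half-missing or fully
        missing calls become the missing sentinel. ``DS`` rounds the dosage
        field to the nearest integer call.
    strict : bool
        If True, a multiallelic record raises; otherwise it is skipped.
    """
    if field not in ("GT", "DS"):
        raise ValueError(f"unsupported genotype field {field!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare exceptions on bad headers
        raise ValueError(f"malformed VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    rows: list[tuple] = []
    calls: list[np.ndarray] = []
    try:
        for i, variant in enumerate(vcf):
            if len(variant.ALT) != 1:
                if strict:
                    raise ValueError(
                        f"multiallelic record {variant.ID or variant.CHROM + ':' + str(variant.POS)} "
                        f"(record {i + 1} of {path})"
                    )
                continue
            rows.append(
                (
                    variant.CHROM,
                    variant.POS,
                    variant.ID or f"{variant.CHROM}:{variant.POS}",
                    variant.REF,
                    variant.ALT[0],
                )
            )
            if not samples:
                calls.append(np.zeros(0, dtype=np.int8))
                continue
            if field == "GT":
                gt = np.asarray(
                    [g[:2] for g in variant.genotypes], dtype=np.int64
                ).reshape(-1, 2)
                dose = gt.sum(axis=1).astype(np.int8)
                dose[(gt < 0).any(axis=1)] = MISSING
            else:
                ds = np.asarray(variant.format("DS"), dtype=float).reshape(-1)
                dose = np.rint(ds).astype(np.int8)
                dose[~np.isfinite(ds)] = MISSING
            calls.append(dose)
    except ValueError:
        raise
    except Exception as exc:
        raise ValueError(
            f"malformed VCF {path} near record {len(rows) + 1}: {exc}"
        ) from exc

    markers = MarkerMap(
        pd.DataFrame(rows, columns=list(MarkerMap.COLUMNS))
        if rows
        else pd.DataFrame(columns=list(MarkerMap.COLUMNS))
    )
    matrix = (
        np.stack(calls, axis=1)
        if calls
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, markers, matrix)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotypes(
    matrix: GenotypeMatrix,
    path: str | os.PathLike,
    posteriors: np.ndarray | None = None,
) -> None:
    """Write a panel as uncompressed VCF 4.2.

    If ``posteriors`` (samples x markers x 3) is given, a GP field with the
    genotype posterior probabilities is emitted alongside GT.
    """
    if posteriors is not None:
        expect = (matrix.n_samples, matrix.n_markers, 3)
        if posteriors.shape != expect:
            raise ValueError(f"posterior tensor shape {posteriors.shape} != {expect}")
    t = matrix.markers.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if posteriors is not None:
            fh.write(
                '##FORMAT=<ID=GP,Number=G,Type=Float,'
                'Description="Genotype posterior probabilities">\n'
            )
        for chrom, grp in t.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        has_samples = matrix.n_samples > 0
        if has_samples:
            header.append("FORMAT")
        fh.write("\t".join(header + matrix.samples) + "\n")
        fmt = "GT" if posteriors is None else "GT:GP"
        for j in range(matrix.n_markers):
            row = t.iloc[j]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(row["id"]),
                row["ref"],
                row["alt"],
                ".",
                "PASS",
                ".",
            ]
            if has_samples:
                fields.append(fmt)
            col = matrix.calls[:, j]
            if posteriors is None:
                fields.extend(_GT_STRINGS[int(d)] for d in col)
            else:
                gp = posteriors[:, j, :]
                fields.extend(
                    f"{_GT_STRINGS[int(d)]}:{p[0]:.6g},{p[1]:.6g},{p[2]:.6g}"
                    for d, p in zip(col, gp)
                )
            fh.write("\t".join(fields) + "\n")


def read_posteriors(path: str | os.PathLike) -> np.ndarray:
    """Read the GP field of a VCF into a samples x markers x 3 tensor."""
    vcf = VCF(str(path))
    n = len(vcf.samples)
    cols = []
    for variant in vcf:
        try:
            gp = variant.format("GP")
        except KeyError:
            gp = None
        if gp is None:
            raise ValueError(f"record {variant.CHROM}:{variant.POS} lacks a GP field")
        cols.append(np.asarray(gp, dtype=float).reshape(n, 3))
    if not cols:
        return np.zeros((n, 0, 3))
    return np.stack(cols, axis=1)
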