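"""Dataset containers, readers/writers and bit-plane pair counting.

Genotypes are held as codes 0/1/2 (AA, Aa, aa; documentation tables use
the 1/2/3 display convention) with 3 as the missing sentinel. For fast
pairwise counting each SNP is expanded into six bit-planes — one boolean
mask per (genotype, phenotype class) — packed 8 subjects per byte; the
3x3x2 contingency table of a pair is then 18 AND + popcount reductions.
This bitwise path is contract-tested to agree exactly with the naive
per-subject tally.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np

from .stats import MISSING, PairCounts, count_pair

__all__ = [
    "GenotypeDataset",
    "read_dataset",
    "write_dataset",
    "write_results",
    "pair_counts_from_bitplanes",
]


class GenotypeDataset:
    """Case-control genotype matrix with per-SNP bit-planes.

    Parameters
    ----------
    genotypes : ndarray of shape (n_subjects, n_snps)
        Codes 0/1/2; 3 marks a missing call.
    phenotype : ndarray of shape (n_subjects,)
        0 = control, 1 = case.
    snp_ids : sequence of str, optional
        Defaults to SNP1..SNPL.
    """

    def __init__(self, genotypes, phenotype, snp_ids=None):
        geno = np.ascontiguousarray(genotypes, dtype=np.int8)
        phen = np.asarray(phenotype, dtype=np.int8)
        if geno.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix (subjects x SNPs)")
        if phen.shape != (geno.shape[0],):
            raise ValueError("phenotype length must equal the number of subjects")
        if not np.isin(geno, (0, 1, 2, MISSING)).all():
            raise ValueError("genotype codes must be 0/1/2 or 3 (missing)")
        if not np.isin(phen, (0, 1)).all():
            raise ValueError("phenotype must be binary 0/1")
        self.genotypes = geno
        self.phenotype = phen
        if snp_ids is None:
            snp_ids = [f"SNP{i + 1}" for i in range(geno.shape[1])]
        if len(snp_ids) != geno.shape[1]:
            raise ValueError("snp_ids length must equal the number of SNPs")
        self.snp_ids = list(snp_ids)
        self._bitplanes: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def bitplanes(self) -> np.ndarray:
        """(L, 3, 2, ceil(n/8)) uint8: packed masks per (SNP, genotype, class)."""
        if self._bitplanes is None:
            geno_t = self.genotypes.T  # (L, n)
            phen = self.phenotype
            planes = []
            for g in range(3):
                per_class = []
                for k in range(2):
                    mask = (geno_t == g) & (phen == k)[None, :]
                    per_class.append(np.packbits(mask, axis=1))
                planes.append(per_class)
            # reorder to (L, 3, 2, W)
            self._bitplanes = np.stack(
                [np.stack(per_class, axis=1) for per_class in planes], axis=1
            )
        return self._bitplanes

    def pair_counts(self, p: int, q: int) -> PairCounts:
        """3x3x2 contingency table of SNPs (p, q) via the bitwise path."""
        return pair_counts_from_bitplanes(self, p, q)

    def pair_counts_block(self, p: int) -> np.ndarray:
        """Count tables of (p, q) for all q > p at once; shape (L-p-1, 3, 3, 2)."""
        if not 0 <= p < self.n_snps - 1:
            raise IndexError(f"SNP index {p} has no partners above it")
        planes = self.bitplanes
        a = planes[p]  # (3, 2, W)
        b = planes[p + 1 :]  # (Q, 3, 2, W)
        joint = a[None, :, None, :, :] & b[:, None, :, :, :]  # (Q, 3, 3, 2, W)
        return np.bitwise_count(joint).sum(axis=-1, dtype=np.int64)

    def subset_snps(self, indices) -> "GenotypeDataset":
        idx = np.asarray(indices)
        return GenotypeDataset(
            self.genotypes[:, idx],
            self.phenotype,
            [self.snp_ids[i] for i in idx],
        )


def pair_counts_from_bitplanes(dataset: GenotypeDataset, p: int, q: int) -> PairCounts:
    """Pair counting by AND + popcount over packed bit-planes.

    Identical by contract to :func:`cescan.stats.count_pair` on the same
    two genotype columns (subjects missing at either SNP fall outside every
    plane intersection, so pairwise deletion is automatic).
    """
    if p == q or not (0 <= p < dataset.n_snps and 0 <= q < dataset.n_snps):
        raise IndexError(f"invalid SNP pair ({p}, {q})")
    planes = dataset.bitplanes
    joint = planes[p][:, None, :, :] & planes[q][None, :, :, :]  # (3, 3, 2, W)
    return PairCounts(np.bitwise_count(joint).sum(axis=-1, dtype=np.int64))


def _parse_boost(text: str, source: str) -> GenotypeDataset:
    rows: list[np.ndarray] = []
    width = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if width is None:
            width = len(tokens)
            if width < 3:
                raise ValueError(
                    f"{source}: line {lineno}: need a phenotype and at least 2 SNPs"
                )
        elif len(tokens) != width:
            raise ValueError(
                f"{source}: line {lineno}: expected {width} fields, got {len(tokens)}"
            )
        converted = [MISSING if t.upper() == "NA" else t for t in tokens]
        try:
            row = np.array(converted, dtype=np.int64)
        except ValueError as exc:
            raise ValueError(f"{source}: line {lineno}: non-numeric field") from exc
        if row[0] not in (0, 1):
            raise ValueError(
                f"{source}: line {lineno}: phenotype must be 0 or 1, got {row[0]}"
            )
        bad = np.flatnonzero(~np.isin(row[1:], (0, 1, 2, MISSING)))
        if bad.size:
            col = int(bad[0]) + 1
            raise ValueError(
                f"{source}: line {lineno}, SNP column {col}: invalid genotype "
                f"code {row[1 + bad[0]]}"
            )
        rows.append(row)
    if not rows:
        raise ValueError(f"{source}: empty dataset")
    data = np.vstack(rows)
    return GenotypeDataset(data[:, 1:], data[:, 0])


def _parse_plink_raw(text: str, source: str) -> GenotypeDataset:
    import pandas as pd

    frame = pd.read_csv(_io.StringIO(text), sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing_cols = [c for c in meta if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{source}: missing .raw header columns {missing_cols}")
    snp_cols = [c for c in frame.columns if c not in meta]
    if len(snp_cols) < 1:
        raise ValueError(f"{source}: no genotype columns found")
    phen = frame["PHENOTYPE"].to_numpy()
    if not np.isin(phen[~np.isnan(phen.astype(float))], (1, 2)).all():
        raise ValueError(f"{source}: PHENOTYPE must be 1 (control) / 2 (case)")
    geno = frame[snp_cols].to_numpy(dtype=float)
    out = np.where(np.isnan(geno), MISSING, geno)
    if not np.isin(out, (0, 1, 2, MISSING)).all():
        raise ValueError(f"{source}: additive genotype codes must be 0/1/2 or NA")
    # strip the _<allele> suffix PLINK appends to SNP names
    ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    return GenotypeDataset(out.astype(np.int8), (phen - 1).astype(np.int8), ids)


def read_dataset(path, format: str = "boost") -> GenotypeDataset:
    """Read a case-control genotype dataset.

    ``boost``: whitespace-delimited, one row per subject, first column the
    0/1 phenotype, then one 0/1/2 genotype code per SNP (3 or NA =
    missing). ``plink-raw``: PLINK ``--recode A`` output with the standard
    six metadata columns, phenotype 1/2 remapped to 0/1.
    """
    path = Path(path)
    text = path.read_text()
    if format == "boost":
        return _parse_boost(text, path.name)
    if format == "plink-raw":
        return _parse_plink_raw(text, path.name)
    raise ValueError(f"unknown dataset format {format!r}")


def write_dataset(dataset: GenotypeDataset, path) -> None:
    """Write a dataset in the BOOST-style text dialect."""
    data = np.column_stack([dataset.phenotype, dataset.genotypes]).astype(np.int64)
    np.savetxt(path, data, fmt="%d", delimiter=" ")


_RESULT_COLUMNS = [
    "snp1_index",
    "snp2_index",
    "snp1_id",
    "snp2_id",
    "screen_stat",
    "best_model",
    "best_stat",
    "p_raw",
    "p_adjusted",
]


def write_results(results, path, all_models: bool = False) -> None:
    """Write scan results as a TSV with deterministic ordering and formatting.

    Statistics carry 6 significant digits; p-values are in scientific
    notation. With ``all_models`` one extra column per non-degenerate model
    class holds that class's statistic.
    """
    lines = []
    header = list(_RESULT_COLUMNS)
    if all_models and results:
        model_labels = sorted(results[0].model_statistics)
        header += [f"M{lab}_stat" for lab in model_labels]
    lines.append("\t".join(header))
    for r in results:
        row = [
            str(r.i),
            str(r.j),
            r.snp1_id,
            r.snp2_id,
            f"{r.screen_statistic:.6g}",
            f"M{r.best_model_label}",
            f"{r.best_statistic:.6g}",
            f"{r.p_raw:.6e}",
            f"{r.p_adjusted:.6e}",
        ]
        if all_models and results:
            row += [f"{r.model_statistics[lab]:.6g}" for lab in model_labels]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
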