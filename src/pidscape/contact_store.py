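"""Binned intra-chromosomal contact matrices: I/O, scaling, merging, coarsening.

The canonical on-disk format is triplet text (TSV): one header line carrying
the bin size, total count and chromosome sizes, then rows of
``chrom  bin1_start  bin2_start  count`` with bin1_start <= bin2_start
(upper triangle; each unordered pair stored once).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .genome import GenomeLayout


class BinnedContacts:
    """Symmetric sparse intra-chromosomal contact counts at fixed bin size.

    Entries are stored canonically as upper-triangle triplets
    (bin_i <= bin_j), one unordered pair once. Counts may be reals after
    depth scaling.
    """

    def __init__(self, layout: GenomeLayout, entries=None, label: str = ""):
        self.layout = layout
        self.label = label
        self._data = {}  # chrom -> (i, j, counts) canonical sorted
        self._sym_cache = {}
        if entries:
            for chrom, (i, j, c) in entries.items():
                self.set_chrom(chrom, i, j, c)

    # -- construction -----------------------------------------------------
    def set_chrom(self, chrom, i, j, counts):
        if chrom not in self.layout.chrom_names:
            raise ValueError(f"unknown chromosome {chrom!r}")
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.float64)
        if np.any(counts < 0):
            raise ValueError("negative count")
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        n = self.layout.n_bins(chrom)
        if lo.size and (lo.min() < 0 or hi.max() >= n):
            raise ValueError(f"bin index outside {chrom}")
        order = np.lexsort((hi, lo))
        lo, hi, counts = lo[order], hi[order], counts[order]
        if lo.size > 1:
            dup = (lo[1:] == lo[:-1]) & (hi[1:] == hi[:-1])
            if dup.any():
                raise ValueError(f"duplicate entry for a bin pair on {chrom}")
        nz = counts != 0
        self._data[chrom] = (lo[nz], hi[nz], counts[nz])
        self._sym_cache.pop(chrom, None)

    def chrom_entries(self, chrom):
        n = self.layout.n_bins(chrom)
        if chrom not in self._data:
            empty = np.array([], dtype=np.int64)
            return empty, empty, np.array([], dtype=np.float64)
        return self._data[chrom]

    @property
    def total_count(self) -> float:
        return float(sum(c.sum() for (_, _, c) in self._data.values()))

    def copy(self, label=None):
        out = BinnedContacts(self.layout, label=self.label if label is None else label)
        for chrom, (i, j, c) in self._data.items():
            out._data[chrom] = (i.copy(), j.copy(), c.copy())
        return out

    def sym_csr(self, chrom) -> sp.csr_matrix:
        """Full symmetric CSR matrix for one chromosome (diagonal once)."""
        if chrom not in self._sym_cache:
            n = self.layout.n_bins(chrom)
            i, j, c = self.chrom_entries(chrom)
            off = i != j
            rows = np.concatenate([i, j[off]])
            cols = np.concatenate([j, i[off]])
            vals = np.concatenate([c, c[off]])
            self._sym_cache[chrom] = sp.csr_matrix(
                (vals, (rows, cols)), shape=(n, n)
            )
        return self._sym_cache[chrom]

    def __eq__(self, other):
        if not isinstance(other, BinnedContacts) or self.layout != other.layout:
            return False
        chroms = set(self._data) | set(other._data)
        for chrom in chroms:
            a, b = self.chrom_entries(chrom), other.chrom_entries(chrom)
            if not all(np.array_equal(x, y) for x, y in zip(a, b)):
                return False
        return True


def write_contacts(m: BinnedContacts, path) -> None:
    bs = m.layout.bin_size
    chroms = ";".join(
        f"{c}:{l}" for c, l in zip(m.layout.chrom_names, m.layout.chrom_lengths)
    )
    total = m.total_count
    total_str = repr(int(total)) if total == int(total) else repr(total)
    with open(path, "w") as fh:
        fh.write(
            f"# pidscape_contacts\tbin_size={bs}\ttotal={total_str}"
            f"\tchroms={chroms}\tlabel={m.label}\n"
        )
        for chrom in m.layout.chrom_names:
            i, j, c = m.chrom_entries(chrom)
            for bi, bj, ct in zip(i, j, c):
                val = repr(int(ct)) if ct == int(ct) else repr(float(ct))
                fh.write(f"{chrom}\t{bi * bs}\t{bj * bs}\t{val}\n")


def read_contacts(path) -> BinnedContacts:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("# pidscape_contacts"):
            raise ValueError(f"{path}:1: missing contacts header")
        fields = dict(
            tok.split("=", 1) for tok in header.split("\t")[1:] if "=" in tok
        )
        bin_size = int(fields["bin_size"])
        total_declared = float(fields["total"])
        chrom_names, chrom_lengths = [], []
        for item in fields["chroms"].split(";"):
            if not item:
                continue
            name, length = item.rsplit(":", 1)
            chrom_names.append(name)
            chrom_lengths.append(int(length))
        layout = GenomeLayout(tuple(chrom_names), tuple(chrom_lengths), bin_size)
        per_chrom = {c: ([], [], []) for c in chrom_names}
        seen = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            chrom, s1, s2, cnt = parts
            if chrom not in per_chrom:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                s1, s2, cnt = int(s1), int(s2), float(cnt)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed line") from exc
            if cnt < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if s1 % bin_size or s2 % bin_size:
                raise ValueError(
                    f"{path}:{lineno}: coordinate not a multiple of bin_size"
                )
            bi, bj = s1 // bin_size, s2 // bin_size
            key = (chrom, min(bi, bj), max(bi, bj))
            if key in seen:
                raise ValueError(
                    f"{path}:{lineno}: bin pair appears more than once "
                    "(both (i,j) and (j,i) present?)"
                )
            seen.add(key)
            if bi > bj:
                raise ValueError(f"{path}:{lineno}: bin_i > bin_j (not canonical)")
            per_chrom[chrom][0].append(bi)
            per_chrom[chrom][1].append(bj)
            per_chrom[chrom][2].append(cnt)
    m = BinnedContacts(layout, label=fields.get("label", ""))
    for chrom, (i, j, c) in per_chrom.items():
        if i:
            m.set_chrom(chrom, i, j, c)
    if not np.isclose(m.total_count, total_declared, rtol=1e-9, atol=1e-6):
        raise ValueError(
            f"{path}: header total {total_declared} != sum of counts {m.total_count}"
        )
    return m


def scale_to_smallest(matrices) -> list:
    """Depth-scale each matrix to the smallest total (hicNormalize-style)."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices")
    layout = matrices[0].layout
    for m in matrices:
        if m.layout != layout:
            raise ValueError("layout mismatch")
    totals = [m.total_count for m in matrices]
    if any(t == 0 for t in totals):
        raise ValueError("cannot scale a matrix with total count 0")
    smallest = min(totals)
    out = []
    for m, t in zip(matrices, totals):
        factor = smallest / t
        scaled = m.copy()
        for chrom in list(scaled._data):
            i, j, c = scaled._data[chrom]
            scaled._data[chrom] = (i, j, c * factor)
        scaled._sym_cache.clear()
        out.append(scaled)
    return out


def merge_replicates(matrices) -> BinnedContacts:
    """Entrywise sum of matrices with identical layout (hicSumMatrices-style)."""
    if not matrices:
        raise ValueError("no matrices to merge")
    layout = matrices[0].layout
    for m in matrices:
        if m.layout != layout:
            raise ValueError("layout mismatch")
    out = BinnedContacts(layout, label="+".join(m.label for m in matrices if m.label))
    for chrom in layout.chrom_names:
        parts = [m.chrom_entries(chrom) for m in matrices]
        i = np.concatenate([p[0] for p in parts])
        j = np.concatenate([p[1] for p in parts])
        c = np.concatenate([p[2] for p in parts])
        if i.size == 0:
            continue
        key = i * np.int64(layout.n_bins(chrom)) + j
        uk, inv = np.unique(key, return_inverse=True)
        sums = np.zeros(uk.size)
        np.add.at(sums, inv, c)
        out.set_chrom(chrom, uk // layout.n_bins(chrom), uk % layout.n_bins(chrom), sums)
    return out


def coarsen(m: BinnedContacts, factor: int) -> BinnedContacts:
    """Aggregate counts into bins `factor` times wider; totals are preserved."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return m.copy()
    new_layout = GenomeLayout(
        m.layout.chrom_names, m.layout.chrom_lengths, m.layout.bin_size * factor
    )
    out = BinnedContacts(new_layout, label=m.label)
    for chrom in m.layout.chrom_names:
        i, j, c = m.chrom_entries(chrom)
        if i.size == 0:
            continue
        ci, cj = i // factor, j // factor
        n = new_layout.n_bins(chrom)
        key = np.minimum(ci, cj) * np.int64(n) + np.maximum(ci, cj)
        uk, inv = np.unique(key, return_inverse=True)
        sums = np.zeros(uk.size)
        np.add.at(sums, inv, c)
        out.set_chrom(chrom, uk // n, uk % n, sums)
    return out
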