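"""Domain types and I/O for codominant microsatellite genotype data.

Alleles are integer fragment sizes (base pairs); a diploid call is an
unordered pair of allele labels, stored sorted.  Missing calls are encoded
as ``(-1, -1)``.  Genotype tables interoperate with GenePop 4.x text files,
two-row STRUCTURE exports, and a lossless CSV dialect with two columns per
locus (``<locus>.1`` / ``<locus>.2``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

_KITS = ("kit-1", "kit-2", "kit-3")


class GenotypeFormatError(ValueError):
    """Raised when a genotype file cannot be parsed or encoded."""


@dataclass(frozen=True)
class Marker:
    """One microsatellite locus of a multiplex panel.

    ``size_range`` is the expected PCR product length range in bp and
    ``kit`` names the multiplex reaction the locus is co-amplified in.
    """

    name: str
    motif: str
    kit: str
    size_range: tuple[int, int]
    dye: str
    library_origin: str = "genomic"

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not lo < hi:
            raise ValueError(f"size_range min must be < max for {self.name}")
        if self.kit not in _KITS:
            raise ValueError(f"unknown kit {self.kit!r} for {self.name}")

    @property
    def repeat_length(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class Panel:
    """An ordered collection of markers partitioned into multiplex kits."""

    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        if len(self.markers) < 1:
            raise ValueError("panel needs at least one marker")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names in panel")

    @property
    def locus_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def kits(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for m in self.markers:
            out.setdefault(m.kit, []).append(m.name)
        return out

    def loci_for_kits(self, kits: Sequence[str]) -> list[str]:
        """Locus names belonging to any of the given kits, in panel order."""
        kitset = set(kits)
        unknown = kitset - set(_KITS)
        if unknown:
            raise ValueError(f"unknown kits: {sorted(unknown)}")
        return [m.name for m in self.markers if m.kit in kitset]

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)


@dataclass
class GenotypeTable:
    """Individuals x loci diploid calls.

    ``calls`` has shape ``(n_individuals, n_loci, 2)`` with allele labels
    sorted within each pair and ``MISSING`` (-1) in both slots of a missing
    call.  ``populations`` optionally labels each individual (e.g. species)
    so a single table can hold several groups.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    populations: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        n, m = len(self.individuals), len(self.loci)
        if self.calls.shape != (n, m, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {m}, 2)")
        self.calls = np.sort(self.calls, axis=2)
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("calls must have 2 alleles or be fully missing")
        if self.populations is not None and len(self.populations) != n:
            raise ValueError("populations length mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"locus {locus!r} not in table") from None

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        idx = [self.locus_index(l) for l in loci]
        return GenotypeTable(list(self.individuals), list(loci),
                             self.calls[:, idx, :],
                             None if self.populations is None
                             else list(self.populations))

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeTable":
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        idx = [pos[i] for i in ids]
        return GenotypeTable(list(ids), list(self.loci), self.calls[idx],
                             None if self.populations is None
                             else [self.populations[i] for i in idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (self.individuals == other.individuals
                and self.loci == other.loci
                and np.array_equal(self.calls, other.calls)
                and (self.populations or None) == (other.populations or None))


def concat_tables(tables: Sequence[GenotypeTable],
                  populations: Sequence[str] | None = None) -> GenotypeTable:
    """Stack tables sharing a locus set; optionally relabel each block."""
    loci = tables[0].loci
    for t in tables[1:]:
        if t.loci != loci:
            raise ValueError("tables must share an identical locus list")
    inds: list[str] = []
    pops: list[str] = []
    for k, t in enumerate(tables):
        inds.extend(t.individuals)
        if populations is not None:
            pops.extend([populations[k]] * t.n_individuals)
        elif t.populations is not None:
            pops.extend(t.populations)
        else:
            pops.extend([f"pop{k + 1}"] * t.n_individuals)
    calls = np.concatenate([t.calls for t in tables], axis=0)
    return GenotypeTable(inds, list(loci), calls, pops)


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele -> frequency mappings for one population."""

    freqs: dict[str, dict[int, float]]
    sample_size: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for locus, f in self.freqs.items():
            tot = sum(f.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(
                    f"frequencies at {locus} sum to {tot}, not 1")
            if any(p <= 0 for p in f.values()):
                raise ValueError(f"non-positive frequency at {locus}")

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)

    def locus_arrays(self, locus: str) -> tuple[np.ndarray, np.ndarray]:
        """(allele labels, probabilities) as aligned numpy arrays."""
        f = self.freqs[locus]
        labels = np.fromiter(f.keys(), dtype=np.int32, count=len(f))
        probs = np.fromiter(f.values(), dtype=float, count=len(f))
        return labels, probs

    def subset_loci(self, loci: Sequence[str]) -> "AlleleFrequencyTable":
        ss = None if self.sample_size is None else {
            l: self.sample_size[l] for l in loci if l in self.sample_size}
        return AlleleFrequencyTable({l: dict(self.freqs[l]) for l in loci}, ss)


@dataclass
class Pedigree:
    """Truth mapping offspring -> (mother, father) plus the sampled pool."""

    parents: dict[str, tuple[str, str]]
    sampled_adults: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for off, (m, f) in self.parents.items():
            if m == f:
                raise ValueError(f"mother == father for offspring {off}")

    def sampled_parents(self, offspring: str) -> set[str]:
        m, f = self.parents[offspring]
        return {p for p in (m, f) if p in self.sampled_adults}


# ---------------------------------------------------------------------------
# GenePop

def _genepop_decode(token: str, line_no: int) -> tuple[int, int]:
    if len(token) == 4:
        w = 2
    elif len(token) == 6:
        w = 3
    else:
        raise GenotypeFormatError(
            f"line {line_no}: genotype token {token!r} is not 4 or 6 digits")
    if not token.isdigit():
        raise GenotypeFormatError(
            f"line {line_no}: non-numeric genotype token {token!r}")
    a, b = int(token[:w]), int(token[w:])
    if a == 0 or b == 0:
        return (MISSING, MISSING)
    return (a, b)


def read_genepop(path) -> GenotypeTable:
    """Read a GenePop 4.x file (2- or 3-digit allele codes).

    The ``0000``/``000000`` code maps to a missing call; population blocks
    are preserved as per-individual population labels ``pop1``, ``pop2``, ...
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenotypeFormatError("empty GenePop file")
    loci: list[str] = []
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        if line.lower() == "pop":
            break
        if not line:
            i += 1
            continue
        if "," in line:
            loci.extend(x.strip() for x in line.split(",") if x.strip())
        else:
            loci.append(line)
        i += 1
    if not loci:
        raise GenotypeFormatError("no locus names before first 'Pop' line")
    if i == len(lines):
        raise GenotypeFormatError("no 'Pop' line found")
    inds: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_no = 0
    for j in range(i, len(lines)):
        raw = lines[j].strip()
        if not raw:
            continue
        if raw.lower() == "pop":
            pop_no += 1
            continue
        if "," not in raw:
            raise GenotypeFormatError(
                f"line {j + 1}: expected 'id , genotypes', got {raw!r}")
        ind, _, geno = raw.partition(",")
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise GenotypeFormatError(
                f"line {j + 1}: {len(tokens)} genotypes for {len(loci)} loci")
        inds.append(ind.strip())
        pops.append(f"pop{pop_no}")
        rows.append([_genepop_decode(t, j + 1) for t in tokens])
    if not inds:
        raise GenotypeFormatError("no individuals found")
    calls = np.array(rows, dtype=np.int32)
    return GenotypeTable(inds, loci, calls, pops)


def write_genepop(table: GenotypeTable, path, title: str = "panelpower export",
                  digits: int = 3) -> None:
    """Write GenePop text; 3-digit encoding by default (sizes exceed 99)."""
    limit = 10 ** digits - 1
    valid = table.calls[table.calls != MISSING]
    if valid.size and (valid.max() > limit or valid.min() < 1):
        raise GenotypeFormatError(
            f"allele labels must lie in [1, {limit}] for {digits}-digit GenePop")
    pops = table.populations or ["pop1"] * table.n_individuals
    order: list[str] = []
    for p in pops:
        if p not in order:
            order.append(p)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        for p in order:
            fh.write("Pop\n")
            for i, ind in enumerate(table.individuals):
                if pops[i] != p:
                    continue
                toks = []
                for a, b in table.calls[i]:
                    if a == MISSING:
                        toks.append("0" * (2 * digits))
                    else:
                        toks.append(f"{a:0{digits}d}{b:0{digits}d}")
                fh.write(f"{ind} ,  " + " ".join(toks) + "\n")


def write_structure(table: GenotypeTable, path) -> None:
    """Two rows per individual, one column per locus, missing = -9."""
    if not np.issubdtype(table.calls.dtype, np.integer):
        raise GenotypeFormatError("allele labels must be integers")
    pops = table.populations or ["pop1"] * table.n_individuals
    pop_code = {p: k + 1 for k, p in enumerate(dict.fromkeys(pops))}
    with open(path, "w") as fh:
        fh.write("\t".join(table.loci) + "\n")
        for i, ind in enumerate(table.individuals):
            for slot in (0, 1):
                row = [ind, str(pop_code[pops[i]])]
                for a in table.calls[i, :, slot]:
                    row.append("-9" if a == MISSING else str(int(a)))
                fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# CSV dialect: one row per individual, two columns per locus.

def write_csv_genotypes(table: GenotypeTable, path) -> None:
    cols: dict[str, list] = {"id": list(table.individuals)}
    if table.populations is not None:
        cols["population"] = list(table.populations)
    for j, locus in enumerate(table.loci):
        for slot in (0, 1):
            vals = table.calls[:, j, slot]
            cols[f"{locus}.{slot + 1}"] = [
                "" if v == MISSING else int(v) for v in vals]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_csv_genotypes(path) -> GenotypeTable:
    df = pd.read_csv(path, dtype={"id": str})
    loci = []
    for c in df.columns:
        if c.endswith(".1"):
            loci.append(c[:-2])
    n, m = len(df), len(loci)
    calls = np.full((n, m, 2), MISSING, dtype=np.int32)
    for j, locus in enumerate(loci):
        for slot in (0, 1):
            col = pd.to_numeric(df[f"{locus}.{slot + 1}"], errors="coerce")
            ok = col.notna().to_numpy()
            calls[ok, j, slot] = col[ok].astype(int)
    pops = df["population"].astype(str).tolist() if "population" in df else None
    return GenotypeTable(df["id"].tolist(), loci, calls, pops)


def write_frequency_csv(freqs: AlleleFrequencyTable, path) -> None:
    rows = []
    for locus, f in freqs.freqs.items():
        for allele, p in f.items():
            rows.append((locus, allele, p))
    pd.DataFrame(rows, columns=["locus", "allele", "frequency"]).to_csv(
        path, index=False)


def read_frequency_csv(path) -> AlleleFrequencyTable:
    df = pd.read_csv(path)
    freqs: dict[str, dict[int, float]] = {}
    for locus, g in df.groupby("locus", sort=False):
        freqs[str(locus)] = dict(
            zip(g["allele"].astype(int), g["frequency"].astype(float)))
    return AlleleFrequencyTable(freqs)


# ---------------------------------------------------------------------------
# Estimation

def estimate_frequencies(table: GenotypeTable) -> AlleleFrequencyTable:
    """Allele frequencies by direct count: count / (2 x non-missing calls)."""
    freqs: dict[str, dict[int, float]] = {}
    sizes: dict[str, int] = {}
    miss = table.missing_mask()
    for j, locus in enumerate(table.loci):
        ok = ~miss[:, j]
        n = int(ok.sum())
        if n == 0:
            raise ValueError(f"locus {locus!r} has no non-missing calls")
        alleles = table.calls[ok, j, :].ravel()
        labels, counts = np.unique(alleles, return_counts=True)
        freqs[locus] = {int(a): c / (2 * n)
                        for a, c in zip(labels, counts)}
        sizes[locus] = n
    return AlleleFrequencyTable(freqs, sizes)


def duplicate_error_rate(table_a: GenotypeTable,
                         table_b: GenotypeTable) -> pd.Series:
    """Per-locus mistyping rate from re-genotyped duplicates.

    For every individual genotyped in both tables, the two unordered calls
    at each locus are matched to minimise disagreement; the rate is
    mismatching allele calls over total compared allele calls (2 per
    non-missing pair).  Pairs with a missing call in either table are
    excluded.  Symmetric in its arguments.
    """
    shared = [i for i in table_a.individuals if i in set(table_b.individuals)]
    if not shared:
        raise ValueError("no overlapping individuals between the two tables")
    loci = [l for l in table_a.loci if l in set(table_b.loci)]
    if not loci:
        raise ValueError("no overlapping loci between the two tables")
    a = table_a.subset_individuals(shared).subset_loci(loci)
    b = table_b.subset_individuals(shared).subset_loci(loci)
    ok = ~(a.missing_mask() | b.missing_mask())
    rates = {}
    for j, locus in enumerate(loci):
        pairs = int(ok[:, j].sum())
        if pairs == 0:
            rates[locus] = np.nan
            continue
        ca, cb = a.calls[ok[:, j], j, :], b.calls[ok[:, j], j, :]
        # minimal matching between two unordered pairs: best of the two
        # possible allele pairings
        m1 = ((ca[:, 0] == cb[:, 0]).astype(int)
              + (ca[:, 1] == cb[:, 1]).astype(int))
        m2 = ((ca[:, 0] == cb[:, 1]).astype(int)
              + (ca[:, 1] == cb[:, 0]).astype(int))
        mism = int((2 - np.maximum(m1, m2)).sum())
        rates[locus] = mism / (2 * pairs)
    return pd.Series(rates, name="error_rate")


# ---------------------------------------------------------------------------
# Packaged fixture

def _data_path(name: str):
    return importlib.resources.files("panelpower.data").joinpath(name)


def load_fixture_panel() -> tuple[Panel, pd.DataFrame]:
    """The packaged 25-locus reference panel and its per-species summary.

    Returns the panel (marker metadata: motif, kit, dye, size range) and a
    long-format DataFrame with the published per-locus, per-species summary
    statistics (Na, Ho, He, Fis, HWE p-value as printed, PE, CumPE) used as
    the verification fixture and as the target profile for the synthetic
    data generator.
    """
    meta = pd.read_csv(_data_path("panel_markers.csv"))
    markers = tuple(
        Marker(name=r.locus, motif=r.motif, kit=r.kit,
               size_range=(int(r.size_min), int(r.size_max)), dye=r.dye,
               library_origin=r.library)
        for r in meta.itertuples())
    panel = Panel(markers)
    summary = pd.read_csv(_data_path("panel_summary.csv"))
    summary["hwe_significant"] = summary["hwe_p"].astype(str).str.startswith("<")
    return panel, summary
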