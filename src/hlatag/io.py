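"""Readers and writers for genotype tables, HLA typing tables and trained
models.

Two genotype dialects are supported:

* ``matrix-tsv`` — a tab-delimited matrix with a header row of SNP ids,
  a first column of sample ids and cells in ``{0,1,2,NA}`` counting
  copies of the counted allele (``allele_b``), plus a companion
  ``.snps`` file with per-SNP metadata.
* ``ped-map`` — text PLINK ped/map pairs with letter alleles and ``0``
  for missing.

Trained models are serialized to a versioned, human-readable key-value
text format that round-trips frequencies to within 1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .nomenclature import AlleleSet, HlaAllele, LOCI, parse_allele

MISSING = -1
_MISSING_TOKENS = {"", "NA", "na", "nan", ".", "-", "-1"}

MODEL_MAGIC = "#hlatag-model"
MODEL_VERSION = "v1"


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


class ValidationError(ValueError):
    """Structurally parseable input violating a table invariant."""


class UnsupportedModelError(ValueError):
    """Model file with an unknown version or a truncated/corrupt body."""


@dataclass(frozen=True)
class SnpRecord:
    """One SNP on chromosome 6 (positions 1-based, build coordinates)."""

    snp_id: str
    chrom: str
    position: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValidationError(f"{self.snp_id}: position must be positive")
        if len(self.allele_a) != 1 or len(self.allele_b) != 1:
            raise ValidationError(f"{self.snp_id}: alleles must be single characters")
        if self.allele_a == self.allele_b:
            raise ValidationError(f"{self.snp_id}: alleles must differ")


class GenotypeTable:
    """Samples x SNPs allele-count matrix.

    ``calls[i, j]`` counts copies of ``snps[j].allele_b`` carried by
    sample ``i`` (0, 1, 2) or is ``MISSING`` (-1).
    """

    def __init__(
        self,
        snps: Sequence[SnpRecord],
        sample_ids: Sequence[str],
        calls: np.ndarray,
    ) -> None:
        self.snps = list(snps)
        self.sample_ids = list(sample_ids)
        self.calls = np.asarray(calls, dtype=np.int8)
        self._validate()

    def _validate(self) -> None:
        if self.calls.shape != (len(self.sample_ids), len(self.snps)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate snp_id in panel")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample_id")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValidationError("genotype calls must be in {0,1,2} or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(snp_id) from None

    def column(self, snp_id: str) -> np.ndarray:
        return self.calls[:, self.snp_index(snp_id)]

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeTable":
        idx = [self.snp_index(s) for s in snp_ids]
        return GenotypeTable(
            [self.snps[i] for i in idx], self.sample_ids, self.calls[:, idx]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return GenotypeTable(self.snps, list(sample_ids), self.calls[idx, :])

    def merge_snps(self, other: "GenotypeTable") -> "GenotypeTable":
        """Column-wise merge of two tables over identical samples,
        re-sorted by position."""
        if other.sample_ids != self.sample_ids:
            raise ValidationError("merge requires identical sample axes")
        overlap = set(self.snp_ids) & set(other.snp_ids)
        if overlap:
            raise ValidationError(f"duplicate snp_id in merge: {sorted(overlap)[:3]}")
        snps = self.snps + other.snps
        calls = np.concatenate([self.calls, other.calls], axis=1)
        order = np.argsort([s.position for s in snps], kind="stable")
        return GenotypeTable([snps[i] for i in order], self.sample_ids, calls[:, order])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, GenotypeTable)
            and self.snps == other.snps
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.calls, other.calls)
        )


class PosteriorGenotypeTable:
    """Samples x SNPs table of genotype probability triples (p0, p1, p2)."""

    def __init__(
        self,
        snps: Sequence[SnpRecord],
        sample_ids: Sequence[str],
        probs: np.ndarray,
    ) -> None:
        self.snps = list(snps)
        self.sample_ids = list(sample_ids)
        self.probs = np.asarray(probs, dtype=float)
        if self.probs.shape != (len(self.sample_ids), len(self.snps), 3):
            raise ValidationError("probs must have shape (n_samples, n_snps, 3)")
        if (self.probs < -1e-12).any() or (self.probs > 1 + 1e-12).any():
            raise ValidationError("genotype probabilities must lie in [0,1]")
        if np.abs(self.probs.sum(axis=2) - 1.0).max() > 1e-6:
            raise ValidationError("genotype probability triples must sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def subset_snps(self, snp_ids: Sequence[str]) -> "PosteriorGenotypeTable":
        pos = {s.snp_id: i for i, s in enumerate(self.snps)}
        idx = [pos[s] for s in snp_ids]
        return PosteriorGenotypeTable(
            [self.snps[i] for i in idx], self.sample_ids, self.probs[:, idx, :]
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "PosteriorGenotypeTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return PosteriorGenotypeTable(self.snps, list(sample_ids), self.probs[idx])


class HlaTypingTable:
    """Per-sample, per-locus HLA truth: two (possibly ambiguous) allele sets."""

    def __init__(self) -> None:
        self._rows: dict[tuple[str, str], tuple[AlleleSet, AlleleSet]] = {}

    def add(
        self, sample_id: str, locus: str, allele1: AlleleSet, allele2: AlleleSet
    ) -> None:
        if locus not in LOCI:
            raise ValidationError(f"unknown locus {locus!r}")
        if allele1.locus != locus or allele2.locus != locus:
            raise ValidationError(
                f"alleles for sample {sample_id} do not belong to locus {locus}"
            )
        key = (sample_id, locus)
        if key in self._rows:
            raise ValidationError(f"duplicate typing row for {sample_id}/{locus}")
        self._rows[key] = (allele1, allele2)

    def get(self, sample_id: str, locus: str):
        return self._rows.get((sample_id, locus))

    def samples(self, locus: str) -> list[str]:
        return [s for (s, l) in self._rows if l == locus]

    def rows(self):
        return [(s, l, a1, a2) for (s, l), (a1, a2) in sorted(self._rows.items())]

    def __len__(self) -> int:
        return len(self._rows)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, HlaTypingTable) and self._rows == other._rows


# ---------------------------------------------------------------------------
# genotype reading / writing


def _snps_companion(path: Path) -> Path:
    return path.with_suffix(".snps")


def _read_snp_metadata(path: Path) -> dict[str, SnpRecord]:
    records: dict[str, SnpRecord] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "snp_id":  # optional header
                continue
            if len(parts) != 5:
                raise ParseError(f"{path}:{ln}: expected 5 columns, got {len(parts)}")
            snp_id, chrom, pos, a, b = parts
            if snp_id in records:
                raise ValidationError(f"{path}:{ln}: duplicate snp_id {snp_id}")
            try:
                rec = SnpRecord(snp_id, chrom, int(pos), a, b)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            records[snp_id] = rec
    return records


def read_genotypes(
    path: str | Path, dialect: str = "matrix-tsv", snps_path: str | Path | None = None
) -> GenotypeTable:
    """Read a genotype table; SNPs are returned sorted by position.

    Unknown genotype tokens map to missing; the reader never invents a
    call for a token it does not recognize as 0/1/2.
    """
    path = Path(path)
    if dialect == "matrix-tsv":
        return _read_matrix_tsv(path, Path(snps_path) if snps_path else _snps_companion(path))
    if dialect == "ped-map":
        return _read_ped_map(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_matrix_tsv(path: Path, snps_path: Path) -> GenotypeTable:
    meta = _read_snp_metadata(snps_path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: header must list sample_id and snp ids")
        snp_ids = header[1:]
        if len(set(snp_ids)) != len(snp_ids):
            raise ValidationError(f"{path}: duplicate snp_id in header")
        missing_meta = [s for s in snp_ids if s not in meta]
        if missing_meta:
            raise ValidationError(
                f"{snps_path}: no metadata for SNPs {missing_meta[:3]}"
            )
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        for ln, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(snp_ids) + 1:
                raise ParseError(
                    f"{path}:{ln}: expected {len(snp_ids) + 1} columns, got {len(parts)}"
                )
            sample_ids.append(parts[0])
            row = []
            for tok in parts[1:]:
                if tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    row.append(MISSING)
            rows.append(row)
    snps = [meta[s] for s in snp_ids]
    calls = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(snps)), np.int8)
    order = np.argsort([s.position for s in snps], kind="stable")
    return GenotypeTable(
        [snps[i] for i in order], sample_ids, calls[:, order] if len(rows) else calls
    )


def _read_ped_map(ped_path: Path) -> GenotypeTable:
    map_path = ped_path.with_suffix(".map")
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            chrom, snp_id, _cm, pos = parts
            map_rows.append((chrom, snp_id, int(pos)))
    ids = [r[1] for r in map_rows]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{map_path}: duplicate snp_id")
    n_snps = len(map_rows)

    sample_ids: list[str] = []
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            allele_rows.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_snps)]
            )

    # Determine allele_a/allele_b per SNP from the observed letters;
    # allele_b (the counted allele) is the lexicographically larger one.
    snps: list[SnpRecord] = []
    calls = np.full((len(sample_ids), n_snps), MISSING, dtype=np.int8)
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        observed = sorted(
            {a for row in allele_rows for a in row[j] if a != "0"}
        )
        if len(observed) > 2:
            raise ValidationError(f"{snp_id}: more than two alleles observed")
        if len(observed) == 2:
            a, b = observed
        elif len(observed) == 1:
            a, b = observed[0], "."  # monomorphic: counted allele unobserved
            a, b = b, a  # count the observed allele so calls are 2, not 0
        else:
            a, b = ".", "?"  # fully missing column
        snps.append(SnpRecord(snp_id, chrom, pos, a, b))
        for i, row in enumerate(allele_rows):
            x, y = row[j]
            if x == "0" or y == "0":
                continue
            calls[i, j] = (x == b) + (y == b)
    order = np.argsort([s.position for s in snps], kind="stable")
    return GenotypeTable([snps[i] for i in order], sample_ids, calls[:, order])


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    """Write a matrix-tsv table plus its ``.snps`` companion."""
    path = Path(path)
    with open(_snps_companion(path), "w") as fh:
        fh.write("snp_id\tchrom\tposition\tallele_a\tallele_b\n")
        for s in table.snps:
            fh.write(f"{s.snp_id}\t{s.chrom}\t{s.position}\t{s.allele_a}\t{s.allele_b}\n")
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(table.snp_ids) + "\n")
        for i, sid in enumerate(table.sample_ids):
            toks = ["NA" if c == MISSING else str(int(c)) for c in table.calls[i]]
            fh.write(sid + "\t" + "\t".join(toks) + "\n")


def read_hla_typing(path: str | Path) -> HlaTypingTable:
    """Read a tsv of sample_id, locus, allele1, allele2.

    Allele cells may be single alleles (``A*0201``/``A*02:01``) or
    ambiguity sets joined by ``/``. Rows with missing allele tokens are
    skipped (missing truth is handled by exclusion downstream).
    """
    table = HlaTypingTable()
    path = Path(path)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "sample_id":
                continue
            if len(parts) != 4:
                raise ParseError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
            sample_id, locus, a1, a2 = parts
            if a1.strip() in _MISSING_TOKENS or a2.strip() in _MISSING_TOKENS:
                continue
            try:
                s1 = AlleleSet.parse(a1, locus)
                s2 = AlleleSet.parse(a2, locus)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            table.add(sample_id, locus, s1, s2)
    return table


def write_hla_typing(table: HlaTypingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlocus\tallele1\tallele2\n")
        for sample_id, locus, a1, a2 in table.rows():
            fh.write(f"{sample_id}\t{locus}\t{a1}\t{a2}\n")


# ---------------------------------------------------------------------------
# model serialization


def write_model(model, path: str | Path) -> None:
    """Serialize a fitted model to the versioned text format.

    Haplotypes with frequency below the model's ``prune_eps`` (or zero)
    are pruned on write; that pruning is part of the format contract.
    """
    path = Path(path)
    items = [
        (jh, f)
        for jh, f in model.freq_items()
        if f > 0 and f >= model.prune_eps
    ]
    with open(path, "w") as fh:
        fh.write(f"{MODEL_MAGIC} {MODEL_VERSION}\n")
        fh.write(f"locus\t{model.locus}\n")
        fh.write(f"resolution\t{model.resolution}\n")
        fh.write(f"n_train\t{model.n_train}\n")
        fh.write(f"prune_eps\t{model.prune_eps:.17g}\n")
        fh.write(f"n_snps\t{model.n_snps}\n")
        for s in model.snps:
            fh.write(
                f"snp\t{s.snp_id}\t{s.chrom}\t{s.position}\t{s.allele_a}\t{s.allele_b}\n"
            )
        fh.write(f"n_haplotypes\t{len(items)}\n")
        for jh, f in items:
            fh.write(f"hap\t{jh.hla}\t{jh.snp_alleles or '-'}\t{f:.17g}\n")
        fh.write("end\n")


def read_model(path: str | Path):
    """Read a model written by :func:`write_model`.

    Raises :class:`UnsupportedModelError` on version mismatch or a
    truncated/corrupt file rather than returning a partial model.
    """
    from .model import HaplotypeModel  # deferred to avoid an import cycle

    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(MODEL_MAGIC):
        raise UnsupportedModelError(f"{path}: not a model file")
    version = lines[0].split()[-1]
    if version != MODEL_VERSION:
        raise UnsupportedModelError(
            f"{path}: unsupported model version {version!r} (expected {MODEL_VERSION})"
        )
    if not lines or lines[-1].strip() != "end":
        raise UnsupportedModelError(f"{path}: truncated model file (missing 'end')")

    kv: dict[str, str] = {}
    snps: list[SnpRecord] = []
    haps: list[tuple[str, str, float]] = []
    for ln, line in enumerate(lines[1:-1], 2):
        parts = line.split("\t")
        if parts[0] == "snp":
            if len(parts) != 6:
                raise UnsupportedModelError(f"{path}:{ln}: malformed snp row")
            snps.append(
                SnpRecord(parts[1], parts[2], int(parts[3]), parts[4], parts[5])
            )
        elif parts[0] == "hap":
            if len(parts) != 4:
                raise UnsupportedModelError(f"{path}:{ln}: malformed hap row")
            haps.append((parts[1], "" if parts[2] == "-" else parts[2], float(parts[3])))
        elif len(parts) == 2:
            kv[parts[0]] = parts[1]
        else:
            raise UnsupportedModelError(f"{path}:{ln}: unrecognized row")
    try:
        locus = kv["locus"]
        resolution = kv["resolution"]
        n_train = int(kv["n_train"])
        prune_eps = float(kv["prune_eps"])
        n_snps = int(kv["n_snps"])
        n_haps = int(kv["n_haplotypes"])
    except KeyError as exc:
        raise UnsupportedModelError(f"{path}: missing header field {exc}") from exc
    if len(snps) != n_snps:
        raise UnsupportedModelError(
            f"{path}: expected {n_snps} snp rows, found {len(snps)}"
        )
    if len(haps) != n_haps:
        raise UnsupportedModelError(
            f"{path}: expected {n_haps} hap rows, found {len(haps)}"
        )
    freqs: dict[tuple[HlaAllele, str], float] = {}
    for hla_text, bits, f in haps:
        allele = parse_allele(hla_text, locus)
        freqs[(allele, bits)] = f
    return HaplotypeModel.from_freqs(
        locus, resolution, snps, freqs, n_train=n_train, prune_eps=prune_eps
    )
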