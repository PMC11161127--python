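"""Reading and writing genotype-phenotype tables and coefficient files.

Genotype-phenotype tables are TSV/CSV with a header and columns
``genotype``, ``phenotype`` and optional ``error``.  String genotypes
are decoded through a per-position allele alphabet (symbol -> state
map with the wild-type symbol first), mandatory because wild-type
symbols generally differ by position.  When no alphabet applies,
genotypes may be given as comma-separated integer states directly.

All machine files are tab-separated UTF-8 with one header row; floats
are serialized with 17 significant digits so round trips are lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .epistasis import CoefficientSet, Landscape
from .regression import ModelSummary
from .state_space import StateSpace

__all__ = [
    "Alphabet",
    "read_landscape",
    "write_landscape",
    "write_coefficients",
    "read_coefficients",
    "write_model_summary",
    "load_trna_example",
    "write_matrix_tsv",
    "write_matrix_sparse",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Alphabet:
    """Per-position symbol lists; index = integer state, entry 0 = wild-type."""

    symbols: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        for k, syms in enumerate(self.symbols, start=1):
            if len(syms) < 2:
                raise ValueError(f"position {k} needs >= 2 symbols")
            if len(set(syms)) != len(syms):
                raise ValueError(f"duplicate symbols at position {k}: {syms}")

    @property
    def space(self) -> StateSpace:
        return StateSpace(tuple(len(s) for s in self.symbols))

    @property
    def single_char(self) -> bool:
        return all(len(sym) == 1 for syms in self.symbols for sym in syms)

    def decode(self, genotype: str) -> tuple[int, ...]:
        """Genotype string -> integer state vector."""
        n = len(self.symbols)
        if "," in genotype:
            parts = genotype.split(",")
        elif self.single_char:
            parts = list(genotype)
        else:
            raise ValueError(
                f"genotype {genotype!r} must be comma-separated for "
                "multi-character allele symbols"
            )
        if len(parts) != n:
            raise ValueError(
                f"genotype {genotype!r} has {len(parts)} symbols, expected {n}"
            )
        states = []
        for k, (sym, syms) in enumerate(zip(parts, self.symbols), start=1):
            try:
                states.append(syms.index(sym))
            except ValueError:
                raise ValueError(
                    f"unknown symbol {sym!r} at position {k} "
                    f"(alphabet {list(syms)})"
                ) from None
        return tuple(states)

    def encode(self, states) -> str:
        syms = [self.symbols[k][a] for k, a in enumerate(states)]
        return "".join(syms) if self.single_char else ",".join(syms)

    def to_dict(self) -> dict:
        return {"schema_version": SCHEMA_VERSION, "positions": [list(s) for s in self.symbols]}

    @classmethod
    def from_dict(cls, d: dict) -> "Alphabet":
        if "positions" not in d:
            raise ValueError("alphabet JSON needs a 'positions' list")
        return cls(tuple(tuple(p) for p in d["positions"]))

    @classmethod
    def integer(cls, space: StateSpace) -> "Alphabet":
        """Plain integer-code alphabet for a space (states as digits)."""
        return cls(tuple(tuple(str(a) for a in range(s)) for s in space.state_counts))


def _parse_states(genotype: str, space: StateSpace) -> tuple[int, ...]:
    parts = genotype.split(",") if "," in genotype else list(genotype)
    try:
        states = tuple(int(p) for p in parts)
    except ValueError:
        raise ValueError(f"genotype {genotype!r} is not integer-coded") from None
    return space.validate_genotype(states)


def read_landscape(
    path, alphabet: Alphabet | None = None, space: StateSpace | None = None
) -> Landscape:
    """Read a genotype-phenotype TSV/CSV into a landscape.

    Exactly one of ``alphabet`` (string genotypes) or ``space``
    (integer-coded genotypes) must be given.  Malformed rows, unknown
    symbols and duplicate genotypes are rejected with their line number.
    """
    if (alphabet is None) == (space is None):
        raise ValueError("provide exactly one of alphabet or space")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"genotype": str}, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no records")
    required = {"genotype", "phenotype"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    sp = alphabet.space if alphabet is not None else space
    phen: dict[int, float] = {}
    err: dict[int, float] = {}
    has_err = "error" in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        gstr = str(row.genotype)
        try:
            states = alphabet.decode(gstr) if alphabet is not None else _parse_states(gstr, sp)
            rank = 1 + int(np.ravel_multi_index(states, sp.state_counts))
            y = float(row.phenotype)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}:{line}: {exc}") from None
        if rank in phen:
            raise ValueError(f"{path}:{line}: duplicate genotype {gstr!r}")
        if not np.isfinite(y):
            continue  # missing phenotype
        phen[rank] = y
        if has_err and np.isfinite(float(row.error)):
            err[rank] = float(row.error)
    if not phen:
        raise ValueError(f"{path}: no records with finite phenotypes")
    return Landscape(sp, phen, err if err else None)


def write_landscape(land: Landscape, path, alphabet: Alphabet | None = None) -> None:
    alphabet = alphabet or Alphabet.integer(land.space)
    ranks = land.observed_ranks()
    from .state_space import vectors_of

    vecs = vectors_of(ranks, land.space)
    rows = {
        "genotype": [alphabet.encode(v) for v in vecs],
        "states": [",".join(map(str, v)) for v in vecs],
        "rank": ranks,
        "phenotype": [land.phenotype[r] for r in ranks],
    }
    if land.error is not None:
        rows["error"] = [land.error.get(r, np.nan) for r in ranks]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def _star_notation(states) -> str:
    return ",".join("*" if a == 0 else str(a) for a in states)


def write_coefficients(coeffs: CoefficientSet, path) -> None:
    """Coefficient TSV: rank, state vector, star notation, order, value,
    propagated error; lossless round trip plus a 2-dp display column."""
    vecs = coeffs.space.all_genotypes()
    df = pd.DataFrame(
        {
            "rank": np.arange(1, coeffs.space.total_size + 1),
            "states": [",".join(map(str, v)) for v in vecs],
            "id": [_star_notation(v) for v in vecs],
            "order": (vecs != 0).sum(axis=1),
            "coefficient": coeffs.value,
        }
    )
    if coeffs.error is not None:
        df["error"] = coeffs.error
    df["pretty"] = [_round_half_away(v, 2) for v in coeffs.value]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_coefficients(path, space: StateSpace) -> CoefficientSet:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if len(df) != space.total_size or not (df["rank"] == np.arange(1, space.total_size + 1)).all():
        raise ValueError("coefficient file does not cover the space in rank order")
    err = df["error"].to_numpy() if "error" in df.columns else None
    return CoefficientSet(space, df["coefficient"].to_numpy(), err)


def write_model_summary(summary: ModelSummary, path) -> None:
    df = summary.table.copy()
    df["id"] = [_star_notation([int(x) for x in s.split(",")]) for s in df["states"]]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (display convention for fixtures)."""
    factor = 10**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def write_matrix_tsv(matrix, path) -> None:
    """Dense transform matrix as TSV with rank headers."""
    df = pd.DataFrame(matrix.values, index=matrix.row_ids, columns=matrix.col_ids)
    df.index.name = "rank"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_matrix_sparse(matrix, path) -> None:
    """Coordinate-format text (row rank, col rank, value), zeros omitted."""
    rows, cols = np.nonzero(matrix.values)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("row\tcol\tvalue\n")
        for r, c in zip(rows, cols):
            fh.write(
                f"{matrix.row_ids[r]}\t{matrix.col_ids[c]}\t"
                f"{matrix.values[r, c]:.17g}\n"
            )


def load_trna_example() -> tuple[Landscape, Alphabet]:
    """Packaged worked example: the 3x3 tRNA-Arg(CCU) sub-landscape.

    All nine combinations of two substitutions each at two paired
    positions (wild-type 'GC'), with measured phenotypic effects
    relative to wild-type and their standard errors.
    """
    data = resources.files("hadamax.data")
    alphabet = Alphabet.from_dict(json.loads(data.joinpath("trna_gc_alphabet.json").read_text()))
    with resources.as_file(data.joinpath("trna_gc_landscape.tsv")) as p:
        return read_landscape(p, alphabet=alphabet), alphabet
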