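"""Reading, writing and validation of concentration time series and reaction lists.

Two plain-text formats are supported, both small enough to inspect by eye:

* **Time-series tables** — delimiter-separated text with a header row, a
  first column named ``time`` (hours), one column per species (nM) and,
  optionally, per-species error columns named ``<species>_err``.
* **Reaction lists** — one reaction per line, ``A -> B ; k ; dk`` where the
  rate constant ``k`` (1/h for unimolecular conversions) and its error
  ``dk`` are optional; ``#`` starts a comment.  Bimolecular mass-action
  reactants/products may be joined with ``+``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "TimeSeriesSet",
    "Reaction",
    "ReactionNetwork",
    "read_timeseries",
    "write_timeseries",
    "resample_uniform",
    "read_reactions",
    "write_reactions",
]


class DataValidationError(ValueError):
    """Raised when an input file or object violates a structural invariant."""


@dataclass
class TimeSeriesSet:
    """Observed concentrations of N species at m time points.

    Parameters
    ----------
    species:
        Unique species identifiers, one per value column.
    times:
        Strictly increasing sampling times in hours, length ``m >= 3``.
    values:
        ``(m, N)`` concentrations in nM.
    errors:
        Optional ``(m, N)`` absolute measurement errors (nM), nonnegative.
    """

    species: list[str]
    times: np.ndarray
    values: np.ndarray
    errors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.species = list(self.species)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
        if len(set(self.species)) != len(self.species):
            dupes = sorted({s for s in self.species if self.species.count(s) > 1})
            raise DataValidationError(f"duplicate species identifiers: {dupes}")
        if self.times.ndim != 1 or self.times.size < 3:
            raise DataValidationError("need at least 3 sampling times")
        if np.any(np.diff(self.times) <= 0):
            k = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 1
            raise DataValidationError(f"non-monotone times at row {k}")
        if self.values.shape != (self.times.size, len(self.species)):
            raise DataValidationError(
                f"values shape {self.values.shape} does not match "
                f"{self.times.size} times x {len(self.species)} species"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise DataValidationError(
                f"non-finite value at row {r}, column {self.species[c]!r}"
            )
        if self.errors is not None:
            if self.errors.shape != self.values.shape:
                raise DataValidationError("errors shape must match values shape")
            if not np.all(np.isfinite(self.errors)) or np.any(self.errors < 0):
                raise DataValidationError("errors must be finite and nonnegative")

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def n_species(self) -> int:
        return len(self.species)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def error_matrix(self, default_relative_error: float = 0.07) -> np.ndarray:
        """Absolute errors; when unmeasured, a relative error of |X| is assumed."""
        if self.errors is not None:
            return self.errors
        return default_relative_error * np.abs(self.values)

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times}
        for k, sp in enumerate(self.species):
            data[sp] = self.values[:, k]
        if self.errors is not None:
            for k, sp in enumerate(self.species):
                data[f"{sp}_err"] = self.errors[:, k]
        return pd.DataFrame(data)


def read_timeseries(path: str | Path | io.TextIOBase, sep: Optional[str] = None) -> TimeSeriesSet:
    """Read a time-series table.

    The first column must parse as time; error columns are recognized by the
    ``<species>_err`` suffix convention.  The delimiter is sniffed from the
    header (tab, comma or whitespace) unless ``sep`` is given; tab- and
    comma-separated files are parsed with round-trip float precision.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    header = text.splitlines()[0] if text else ""
    if sep is None:
        sep = "\t" if "\t" in header else ("," if "," in header else r"\s+")
    try:
        if sep in ("\t", ",", ";"):
            frame = pd.read_csv(
                io.StringIO(text), sep=sep, comment="#", float_precision="round_trip"
            )
        else:
            frame = pd.read_csv(io.StringIO(text), sep=sep, engine="python", comment="#")
    except ValueError as exc:
        raise DataValidationError(f"could not parse table: {exc}") from exc
    if frame.shape[1] < 2:
        raise DataValidationError("need a time column and at least one species column")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            bad = frame[col].map(lambda v: not isinstance(v, (int, float))).idxmax()
            raise DataValidationError(
                f"non-numeric cell at row {bad}, column {col!r}"
            )
    time_col = frame.columns[0]
    species = [c for c in frame.columns[1:] if not c.endswith("_err")]
    err_cols = [c for c in frame.columns[1:] if c.endswith("_err")]
    errors = None
    if err_cols:
        expected = [f"{s}_err" for s in species]
        if sorted(err_cols) != sorted(expected):
            raise DataValidationError(
                f"error columns {sorted(err_cols)} do not match species columns"
            )
        errors = frame[expected].to_numpy(dtype=float)
    return TimeSeriesSet(
        species=species,
        times=frame[time_col].to_numpy(dtype=float),
        values=frame[species].to_numpy(dtype=float),
        errors=errors,
    )


def write_timeseries(ts: TimeSeriesSet, path: str | Path) -> None:
    """Write ``ts`` as a tab-separated table (exact inverse of :func:`read_timeseries`)."""
    ts.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def resample_uniform(ts: TimeSeriesSet, step: Optional[float] = None) -> TimeSeriesSet:
    """Resample onto an arithmetic time grid.

    Values are interpolated with a monotone, overshoot-free piecewise-cubic
    interpolant (PCHIP), which is exact on affine series and never leaves the
    range of a monotone segment; errors are interpolated linearly.  The
    default step is the smallest observed inter-sample gap.
    """
    span = ts.times[-1] - ts.times[0]
    if step is None:
        step = float(np.min(np.diff(ts.times)))
    if step <= 0:
        raise DataValidationError("step must be positive")
    if step > span / 2:
        raise DataValidationError(
            f"step {step} larger than half the observed span {span}"
        )
    n = int(np.floor(span / step + 1e-9)) + 1
    new_times = ts.times[0] + step * np.arange(n)
    values = np.column_stack(
        [PchipInterpolator(ts.times, ts.values[:, k])(new_times) for k in range(ts.n_species)]
    )
    errors = None
    if ts.errors is not None:
        errors = np.column_stack(
            [np.interp(new_times, ts.times, ts.errors[:, k]) for k in range(ts.n_species)]
        )
    return TimeSeriesSet(species=ts.species, times=new_times, values=values, errors=errors)


@dataclass(frozen=True)
class Reaction:
    """A mass-action conversion ``reactants -> products`` with optional rate."""

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: Optional[float] = None
    rate_error: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rate is not None and self.rate < 0:
            raise DataValidationError(f"reaction {self.id}: rate must be >= 0")
        if self.rate_error is not None and self.rate_error < 0:
            raise DataValidationError(f"reaction {self.id}: rate error must be >= 0")
        if not self.reactants or not self.products:
            raise DataValidationError(f"reaction {self.id}: empty side")

    @property
    def reactant(self) -> str:
        """Sole reactant of a unimolecular conversion."""
        if len(self.reactants) != 1:
            raise ValueError(f"reaction {self.id} is not unimolecular")
        return self.reactants[0]

    @property
    def product(self) -> str:
        if len(self.products) != 1:
            raise ValueError(f"reaction {self.id} is not unimolecular")
        return self.products[0]

    def format(self) -> str:
        line = f"{' + '.join(self.reactants)} -> {' + '.join(self.products)}"
        if self.rate is not None:
            line += f" ; {self.rate:.17g}"
            if self.rate_error is not None:
                line += f" ; {self.rate_error:.17g}"
        return line


@dataclass
class ReactionNetwork:
    """An ordered list of reactions over a species universe."""

    reactions: list[Reaction] = field(default_factory=list)
    species_universe: Optional[list[str]] = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate reaction ids: {dupes}")
        if self.species_universe is not None:
            universe = set(self.species_universe)
            for r in self.reactions:
                missing = (set(r.reactants) | set(r.products)) - universe
                if missing:
                    raise DataValidationError(
                        f"reaction {r.id} references unknown species {sorted(missing)}"
                    )

    @property
    def species(self) -> list[str]:
        """Species in order of first appearance (universe order if given)."""
        if self.species_universe is not None:
            return list(self.species_universe)
        seen: dict[str, None] = {}
        for r in self.reactions:
            for s in r.reactants + r.products:
                seen.setdefault(s)
        return list(seen)

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self):
        return iter(self.reactions)

    def get(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def pairs(self) -> set[tuple[tuple[str, ...], tuple[str, ...]]]:
        return {(r.reactants, r.products) for r in self.reactions}


def _parse_side(text: str, lineno: int) -> tuple[str, ...]:
    names = tuple(part.strip() for part in text.split("+"))
    if any(not n for n in names):
        raise DataValidationError(f"malformed species list at line {lineno}: {text!r}")
    return names


def read_reactions(
    path: str | Path | io.TextIOBase,
    species_universe: Optional[Sequence[str]] = None,
    unknown_species: str = "collect",
) -> ReactionNetwork:
    """Parse a reaction list.

    ``unknown_species`` is either ``"collect"`` (species named in reactions
    are accepted into the universe) or ``"reject"`` (reactions naming species
    outside ``species_universe`` are an error).
    """
    if unknown_species not in ("collect", "reject"):
        raise ValueError("unknown_species must be 'collect' or 'reject'")
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    reactions: list[Reaction] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        rid = None
        if ":" in line.split("->")[0]:
            rid, line = (part.strip() for part in line.split(":", 1))
        parts = [p.strip() for p in line.split(";")]
        if "->" not in parts[0] or len(parts) > 3:
            raise DataValidationError(f"malformed reaction at line {lineno}: {raw!r}")
        lhs, _, rhs = parts[0].partition("->")
        try:
            rate = float(parts[1]) if len(parts) > 1 else None
            rate_error = float(parts[2]) if len(parts) > 2 else None
        except ValueError:
            raise DataValidationError(
                f"malformed rate constant at line {lineno}: {raw!r}"
            ) from None
        reactions.append(
            Reaction(
                id=rid if rid is not None else f"R{len(reactions) + 1}",
                reactants=_parse_side(lhs, lineno),
                products=_parse_side(rhs, lineno),
                rate=rate,
                rate_error=rate_error,
            )
        )
    universe = list(species_universe) if species_universe is not None else None
    if unknown_species == "collect":
        universe = None if universe is None else universe
        net = ReactionNetwork(reactions=reactions)
        if universe is not None:
            extra = [s for s in net.species if s not in universe]
            net.species_universe = universe + extra
            net.__post_init__()
        return net
    return ReactionNetwork(reactions=reactions, species_universe=universe)


def write_reactions(net: ReactionNetwork, path: str | Path | io.TextIOBase) -> None:
    """Write a reaction list (exact inverse of :func:`read_reactions`)."""
    lines = [f"{r.id}: {r.format()}" for r in net.reactions]
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(path, (str, Path)):
        Path(path).write_text(text)
    else:
        path.write(text)
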