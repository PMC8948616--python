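"""Reading, writing and validation of feature tables and reaction networks.

A :class:`FeatureTable` is the central in-memory container: a samples x
features matrix of calibrated metabolite values (Intensities, Ratios or
Concs — the calibration level is declared by the experiment configuration,
never inferred from the file) together with per-sample metadata: a class
label, a replicate group naming the biological condition whose replicates
may be pooled, and optional batch id and biomass.

Reaction networks use a deliberately minimal flat-text format,
``id: 2 a + b -> c + d``, because only stoichiometry enters the
mass-action-ratio computation; SBML import is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "Reaction",
    "ReactionNetwork",
    "read_feature_table",
    "write_feature_table",
    "read_reaction_network",
    "write_reaction_network",
]

#: metadata column names recognised (case-insensitively) on disk
RESERVED_COLUMNS = ("label", "replicate_group", "batch", "biomass")


class TableFormatError(ValueError):
    """Raised when a feature table or reaction network violates an invariant."""


@dataclass
class FeatureTable:
    """Samples x features matrix with per-sample metadata.

    Missing values are ``NaN`` in :attr:`values`.  ``biomass``, when
    present, must be strictly positive; every sample carries a label and a
    replicate group.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray  # (n_samples, n_features), float, NaN = missing
    labels: list[str]
    replicate_group: list[str]
    batch: list[str] | None = None
    biomass: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.biomass is not None:
            self.biomass = np.asarray(self.biomass, dtype=float)
        self.validate()

    # -- structural invariants -------------------------------------------------
    def validate(self) -> None:
        n, p = self.values.shape if self.values.ndim == 2 else (len(self.values), -1)
        if self.values.ndim != 2:
            raise TableFormatError("values must be a 2-D matrix")
        if len(self.sample_ids) != n:
            raise TableFormatError(
                f"row count {n} != number of sample ids {len(self.sample_ids)}"
            )
        if len(self.feature_ids) != p:
            raise TableFormatError(
                f"column count {p} != number of feature ids {len(self.feature_ids)}"
            )
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise TableFormatError(f"duplicate {name} ids: {sorted(dupes)}")
        for name, col in (("labels", self.labels), ("replicate_group", self.replicate_group)):
            if len(col) != n:
                raise TableFormatError(f"{name} has {len(col)} entries for {n} samples")
            if any(v is None or str(v) == "" or (isinstance(v, float) and np.isnan(v)) for v in col):
                raise TableFormatError(f"every sample must have a non-empty {name} entry")
        if self.batch is not None and len(self.batch) != n:
            raise TableFormatError("batch has wrong length")
        if self.biomass is not None:
            if len(self.biomass) != n:
                raise TableFormatError("biomass has wrong length")
            if not np.all(np.isfinite(self.biomass)) or np.any(self.biomass <= 0):
                raise TableFormatError("biomass must be strictly positive for all samples")

    # -- convenience -----------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def with_values(self, values: np.ndarray, feature_ids: list[str] | None = None) -> "FeatureTable":
        """Copy of the table with a new value matrix (and optionally new features)."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            feature_ids=list(feature_ids) if feature_ids is not None else list(self.feature_ids),
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)
        df.insert(0, "label", self.labels)
        df.insert(1, "replicate_group", self.replicate_group)
        pos = 2
        if self.batch is not None:
            df.insert(pos, "batch", self.batch)
            pos += 1
        if self.biomass is not None:
            df.insert(pos, "biomass", self.biomass)
        df.index.name = "sample_id"
        return df


def _duplicates(ids) -> set:
    seen, dup = set(), set()
    for x in ids:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# feature-table I/O
# ---------------------------------------------------------------------------

def read_feature_table(path, sep: str = ",", na_sentinel: str = "NA") -> FeatureTable:
    """Read a delimited feature table.

    The header row names the features; the first column holds sample ids.
    Metadata columns named ``label``, ``replicate_group``, ``batch`` and
    ``biomass`` (any case) are pulled out of the matrix.  Empty cells and
    ``na_sentinel`` become missing values.

    Raises
    ------
    TableFormatError
        On duplicate sample/feature ids or a non-numeric value cell (the
        error names the offending row and column).
    """
    with open(path) as fh:
        cols = fh.readline().rstrip("\n").split(sep)[1:]  # pandas mangles duplicates
    dupes = _duplicates(cols)
    if dupes:
        raise TableFormatError(f"duplicate feature ids in header of {path}: {sorted(dupes)}")

    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str,
        keep_default_na=False, na_values=["", na_sentinel],
    )
    dupes = _duplicates(list(df.index))
    if dupes:
        raise TableFormatError(f"duplicate sample ids in {path}: {sorted(dupes)}")

    meta = {}
    for col in list(df.columns):
        if col.lower() in RESERVED_COLUMNS:
            meta[col.lower()] = df[col]
            df = df.drop(columns=[col])

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(raw)
            except ValueError:
                raise TableFormatError(
                    f"non-numeric value {raw!r} at row {df.index[i]!r}, column {col!r}"
                ) from None

    if "label" not in meta or "replicate_group" not in meta:
        raise TableFormatError(
            "feature table must contain 'label' and 'replicate_group' metadata columns"
        )
    biomass = None
    if "biomass" in meta:
        biomass = meta["biomass"].astype(float).to_numpy()
    return FeatureTable(
        sample_ids=[str(s) for s in df.index],
        feature_ids=[str(c) for c in df.columns],
        values=values,
        labels=[str(v) for v in meta["label"]],
        replicate_group=[str(v) for v in meta["replicate_group"]],
        batch=[str(v) for v in meta["batch"]] if "batch" in meta else None,
        biomass=biomass,
    )


def write_feature_table(table: FeatureTable, path, sep: str = ",") -> None:
    """Write a feature table; missing values become empty cells.

    Values round-trip bit-exactly through :func:`read_feature_table`
    (floats are written with ``repr`` precision).
    """
    df = table.to_dataframe()
    df.to_csv(path, sep=sep, na_rep="", float_format=None)


# ---------------------------------------------------------------------------
# reaction networks
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    """A reaction with positive stoichiometric coefficients.

    Reactant and product metabolite sets must be disjoint.
    """

    id: str
    reactants: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.reactants) & set(self.products)
        if overlap:
            raise TableFormatError(
                f"reaction {self.id!r}: metabolites on both sides: {sorted(overlap)}"
            )
        for side in (self.reactants, self.products):
            for met, coef in side.items():
                if not coef > 0:
                    raise TableFormatError(
                        f"reaction {self.id!r}: non-positive coefficient for {met!r}"
                    )

    @property
    def participants(self) -> set[str]:
        return set(self.reactants) | set(self.products)

    def reversed(self) -> "Reaction":
        return Reaction(id=self.id, reactants=dict(self.products), products=dict(self.reactants))


@dataclass
class ReactionNetwork:
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        dupes = _duplicates([r.id for r in self.reactions])
        if dupes:
            raise TableFormatError(f"duplicate reaction ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self):
        return iter(self.reactions)


_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def _parse_side(text: str, rxn_id: str, lineno: int) -> dict[str, float]:
    side: dict[str, float] = {}
    for term in text.split("+"):
        if not term.strip():
            raise TableFormatError(f"line {lineno}: empty term in reaction {rxn_id!r}")
        if term.strip().startswith("-"):
            raise TableFormatError(
                f"line {lineno}: negative coefficient in reaction {rxn_id!r}: {term.strip()!r}"
            )
        m = _TERM_RE.match(term)
        if m is None:
            raise TableFormatError(f"line {lineno}: cannot parse term {term.strip()!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        side[met] = side.get(met, 0.0) + coef
    return side


def read_reaction_network(path) -> ReactionNetwork:
    """Parse a flat-text reaction file, one ``id: lhs -> rhs`` per line.

    Terms are ``+``-separated ``coef metabolite`` pairs with an implicit
    coefficient of 1.  Blank lines and ``#`` comments are skipped.  Errors
    report the 1-based line number.
    """
    reactions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise TableFormatError(f"line {lineno}: missing 'id:' prefix")
            rxn_id, _, rest = line.partition(":")
            rxn_id = rxn_id.strip()
            if "->" not in rest:
                raise TableFormatError(f"line {lineno}: missing '->' arrow in {rxn_id!r}")
            lhs, _, rhs = rest.partition("->")
            try:
                reaction = Reaction(
                    id=rxn_id,
                    reactants=_parse_side(lhs, rxn_id, lineno),
                    products=_parse_side(rhs, rxn_id, lineno),
                )
            except TableFormatError as err:
                raise TableFormatError(f"line {lineno}: {err}") from None
            reactions.append(reaction)
    return ReactionNetwork(reactions=reactions)


def write_reaction_network(network: ReactionNetwork, path) -> None:
    def fmt(side: dict[str, float]) -> str:
        parts = []
        for met, coef in side.items():
            parts.append(met if coef == 1 else f"{coef:g} {met}")
        return " + ".join(parts)

    with open(path, "w") as fh:
        for r in network:
            fh.write(f"{r.id}: {fmt(r.reactants)} -> {fmt(r.products)}\n")
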