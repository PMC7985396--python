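"""Reaction datasets: domain types, flat-file I/O and EC-number resolution.

A *reaction dataset* is the biochemical inventory of one organism (genome) or
one ecosystem sample (metagenome): the set of chemical reactions its annotated
enzymes can catalyse.  Each reaction is an identifier plus the sets of compound
identifiers on its substrate and product sides.  Stoichiometric coefficients
are deliberately dropped — every downstream network projection depends only on
which compounds participate in which reactions, not on how many copies.

Interchange formats are deliberately minimal:

* reaction table — TSV ``reaction_id<TAB>substrates<TAB>products`` with
  comma-separated compound lists inside the last two fields, or a JSON list of
  ``{"reaction_id": ..., "substrates": [...], "products": [...]}`` objects;
* EC lookup table — TSV ``ec_number<TAB>reaction_ids`` (comma-separated), used
  to resolve enzyme annotations (EC numbers) into reaction sets the way a
  KEGG-style ENZYME->REACTION lookup would.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

logger = logging.getLogger(__name__)

Level = Literal["individual", "ecosystem"]
LEVELS: tuple[str, str] = ("individual", "ecosystem")

#: dotted 4-field EC pattern; trailing fields may be wildcards ("-" or "n?")
_EC_RE = re.compile(r"^\d+\.(?:\d+|-)\.(?:\d+|-)\.(?:n?\d+|-)$")


class ReactionFormatError(ValueError):
    """Malformed reaction table or EC map content."""


@dataclass(frozen=True)
class Reaction:
    """One biochemical transformation: substrate and product compound sets."""

    reaction_id: str
    substrates: frozenset[str]
    products: frozenset[str]

    def __post_init__(self) -> None:
        if not self.reaction_id:
            raise ReactionFormatError("reaction_id must be nonempty")
        object.__setattr__(self, "substrates", frozenset(self.substrates))
        object.__setattr__(self, "products", frozenset(self.products))
        if not (self.substrates | self.products):
            raise ReactionFormatError(
                f"reaction {self.reaction_id!r}: substrates and products both empty"
            )
        for c in self.substrates | self.products:
            if not isinstance(c, str) or not c:
                raise ReactionFormatError(
                    f"reaction {self.reaction_id!r}: compound ids must be nonempty strings"
                )

    @property
    def compounds(self) -> frozenset[str]:
        return self.substrates | self.products


@dataclass
class ReactionDataset:
    """A labelled reaction set standing in for one genome or metagenome."""

    dataset_id: str
    level: Level
    reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if not self.reactions:
            raise ValueError(f"dataset {self.dataset_id!r} has no reactions")
        seen: dict[str, Reaction] = {}
        deduped: list[Reaction] = []
        for rxn in self.reactions:
            prev = seen.get(rxn.reaction_id)
            if prev is None:
                seen[rxn.reaction_id] = rxn
                deduped.append(rxn)
            elif prev != rxn:
                raise ReactionFormatError(
                    f"duplicate reaction_id {rxn.reaction_id!r} with conflicting sides"
                )
        self.reactions = deduped

    @property
    def compounds(self) -> frozenset[str]:
        out: set[str] = set()
        for rxn in self.reactions:
            out |= rxn.compounds
        return frozenset(out)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.reaction_id for r in self.reactions]

    def __len__(self) -> int:
        return len(self.reactions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReactionDataset):
            return NotImplemented
        return (
            self.dataset_id == other.dataset_id
            and self.level == other.level
            and set(self.reactions) == set(other.reactions)
        )


@dataclass
class ECMap:
    """EC-number -> reaction-id lookup (a flat KEGG-ENZYME-style table)."""

    entries: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for ec in self.entries:
            if not _EC_RE.match(ec):
                raise ReactionFormatError(f"invalid EC number {ec!r}")
        self.entries = {ec: frozenset(v) for ec, v in self.entries.items()}

    def validate_against(self, reactions: Iterable[Reaction]) -> None:
        """Every mapped reaction_id must resolve against the reaction table."""
        known = {r.reaction_id for r in reactions}
        for ec, rids in self.entries.items():
            missing = rids - known
            if missing:
                raise ReactionFormatError(
                    f"EC {ec} maps to unknown reaction ids {sorted(missing)}"
                )


def _split_compounds(fld: str) -> frozenset[str]:
    return frozenset(c.strip() for c in fld.split(",") if c.strip())


def read_reaction_table(path: str | Path, level: Level,
                        dataset_id: str | None = None) -> ReactionDataset:
    """Read a TSV (or ``.json``) reaction table into a validated dataset.

    Identical duplicate rows are collapsed; the same reaction_id with
    conflicting substrate/product sides raises :class:`ReactionFormatError`
    with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dataset_id is None:
        dataset_id = path.stem
    if path.suffix.lower() == ".json":
        return _read_reaction_json(path, level, dataset_id)
    reactions: list[Reaction] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() == "reaction_id":
                continue  # optional header
            if len(parts) != 3:
                raise ReactionFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            rid, subs, prods = (p.strip() for p in parts)
            try:
                reactions.append(
                    Reaction(rid, _split_compounds(subs), _split_compounds(prods))
                )
            except ReactionFormatError as exc:
                raise ReactionFormatError(f"{path}:{lineno}: {exc}") from exc
    return ReactionDataset(dataset_id, level, reactions)


def _read_reaction_json(path: Path, level: Level, dataset_id: str) -> ReactionDataset:
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise ReactionFormatError(f"{path}: JSON reaction table must be a list")
    reactions = [
        Reaction(
            rec["reaction_id"],
            frozenset(rec.get("substrates", [])),
            frozenset(rec.get("products", [])),
        )
        for rec in records
    ]
    return ReactionDataset(dataset_id, level, reactions)


def write_reaction_table(dataset: ReactionDataset, path: str | Path) -> None:
    """Write the TSV form read back by :func:`read_reaction_table`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("reaction_id\tsubstrates\tproducts\n")
        for rxn in dataset.reactions:
            fh.write(
                f"{rxn.reaction_id}\t{','.join(sorted(rxn.substrates))}"
                f"\t{','.join(sorted(rxn.products))}\n"
            )


def read_ec_map(path: str | Path) -> ECMap:
    """Read a TSV ``ec_number<TAB>reaction_ids`` lookup table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() == "ec_number":
                continue
            if len(parts) != 2:
                raise ReactionFormatError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            ec = parts[0].strip()
            entries.setdefault(ec, set()).update(
                r.strip() for r in parts[1].split(",") if r.strip()
            )
    return ECMap({ec: frozenset(v) for ec, v in entries.items()})


def resolve_ec_list(
    ec_numbers: Sequence[str],
    ec_map: ECMap | Mapping[str, Iterable[str]],
    reaction_table: Sequence[Reaction],
    level: Level,
    dataset_id: str = "resolved",
) -> ReactionDataset:
    """Resolve an enzyme (EC) annotation list into a reaction dataset.

    The result is the union of all reactions any listed EC maps to;
    multiplicity is ignored.  ECs absent from the lookup table are logged and
    skipped.  An empty resolved set is an error.
    """
    entries = ec_map.entries if isinstance(ec_map, ECMap) else dict(ec_map)
    by_id = {r.reaction_id: r for r in reaction_table}
    resolved: set[str] = set()
    for ec in dict.fromkeys(ec_numbers):  # order-stable dedup
        rids = entries.get(ec)
        if rids is None:
            logger.warning("EC %s not in lookup table; skipped", ec)
            continue
        resolved |= set(rids)
    missing = resolved - by_id.keys()
    if missing:
        raise ReactionFormatError(
            f"EC map references reactions absent from the table: {sorted(missing)}"
        )
    if not resolved:
        raise ReactionFormatError("no EC number resolved to any reaction")
    reactions = [by_id[rid] for rid in sorted(resolved)]
    return ReactionDataset(dataset_id, level, reactions)
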