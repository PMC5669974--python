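"""Two-sample RPPA endpoint tables: parsing, ratio ranking, and node mapping.

A reverse-phase protein array (RPPA) panel measures the expression or
phosphorylation level of many signaling proteins as positive intensities in
arbitrary units.  Here the panel compares two tumour samples -- a
long-overall-survival patient (l-OS) and a short-overall-survival patient
(s-OS) -- and the quantity of interest for every antibody endpoint is the
ratio s-OS / l-OS.  Endpoints whose ratio deviates strongly from 1 mark
proteins whose activation differs between the two patients; the most
divergent endpoints that map onto the pathway model become the calibration
targets of the downstream robustness analysis.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

#: ratio flags
FINITE = "finite"
UNDEFINED_HIGH = "undefined-high"   # l-OS = 0, s-OS > 0: divergent upward, no finite value
UNINFORMATIVE = "uninformative"     # both intensities zero

REQUIRED_COLUMNS = ("catalog_id", "antibody", "l_OS", "s_OS")


class RppaFormatError(ValueError):
    """The input table does not have the expected shape or columns."""


class RppaValidationError(ValueError):
    """A row violates an invariant (e.g. negative intensity)."""


class MappingError(KeyError):
    """An endpoint has no entry in the antibody-to-node mapping."""


class SelectionError(RuntimeError):
    """Calibration-protein selection is impossible on this table."""


def compute_ratio(value_lOS: float, value_sOS: float) -> tuple[float, str]:
    """Return ``(ratio, flag)`` for one endpoint.

    The ratio is s-OS / l-OS.  A zero denominator with a positive numerator
    yields ``nan`` flagged ``undefined-high`` (divergent upward without a
    finite value); two zeros are ``uninformative``.
    """
    if value_lOS < 0 or value_sOS < 0:
        raise RppaValidationError(
            f"negative intensity: l_OS={value_lOS}, s_OS={value_sOS}"
        )
    if value_lOS == 0.0:
        if value_sOS == 0.0:
            return math.nan, UNINFORMATIVE
        return math.nan, UNDEFINED_HIGH
    return value_sOS / value_lOS, FINITE


@dataclass(frozen=True)
class RppaEndpoint:
    """One antibody measurement (a phosphosite or a total protein)."""

    catalog_id: str
    antibody: str
    value_lOS: float
    value_sOS: float
    company: str = ""
    dilution: str = ""
    printed_ratio: float | None = None

    def __post_init__(self) -> None:
        ratio, flag = compute_ratio(self.value_lOS, self.value_sOS)
        object.__setattr__(self, "ratio", ratio)
        object.__setattr__(self, "ratio_flag", flag)

    ratio: float = field(init=False)
    ratio_flag: str = field(init=False)

    @property
    def divergence_score(self) -> float:
        """Signed divergence: log2(ratio), with +/-inf for undefined/zero ratios.

        Endpoints without a finite positive ratio are ranked most extreme on
        their side but carry no usable log-scale target value.
        """
        if self.ratio_flag == UNDEFINED_HIGH:
            return math.inf
        if self.ratio_flag == UNINFORMATIVE:
            return math.nan
        if self.ratio == 0.0:
            return -math.inf
        return math.log2(self.ratio)


@dataclass
class RppaTable:
    """An ordered two-sample RPPA panel."""

    endpoints: list[RppaEndpoint]
    sample_labels: tuple[str, str] = ("l-OS", "s-OS")

    def __post_init__(self) -> None:
        names = [e.antibody for e in self.endpoints]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RppaValidationError(f"duplicate antibody names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.endpoints)

    def __iter__(self):
        return iter(self.endpoints)

    def get(self, antibody: str) -> RppaEndpoint:
        for e in self.endpoints:
            if e.antibody == antibody:
                return e
        raise KeyError(antibody)


@dataclass
class DivergenceSelection:
    """Result of divergence thresholding and/or calibration-protein choice."""

    divergent_endpoints: list[RppaEndpoint] = field(default_factory=list)
    up_in_sOS: list[RppaEndpoint] = field(default_factory=list)
    down_in_sOS: list[RppaEndpoint] = field(default_factory=list)
    #: model node -> +1 (higher in s-OS) or -1 (lower in s-OS)
    calibration_proteins: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        up = {e.antibody for e in self.up_in_sOS}
        down = {e.antibody for e in self.down_in_sOS}
        if up & down:
            raise RppaValidationError(f"up/down subsets overlap: {up & down}")


def _parse_float(text: str, column: str, line: int) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise RppaFormatError(f"line {line}: bad {column} value {text!r}") from exc


def load_rppa_table(path: str | Path, dialect: str | None = None) -> RppaTable:
    """Read a CSV/TSV RPPA table.

    Required columns: ``catalog_id, antibody, l_OS, s_OS``; ``company``,
    ``dilution`` and a ``printed_ratio`` column are optional.  Ratios are
    always recomputed from the raw intensities; when a printed ratio column
    is present it is cross-checked to 2 decimals and mismatches are logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    return parse_rppa_table(text, dialect=dialect, source=str(path))


def parse_rppa_table(
    text: str, dialect: str | None = None, source: str = "<string>"
) -> RppaTable:
    if not text.strip():
        raise RppaFormatError(f"{source}: empty RPPA table")
    if dialect is None:
        header = text.splitlines()[0]
        dialect = "\t" if "\t" in header else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=dialect)
    cols = reader.fieldnames or []
    missing = [c for c in REQUIRED_COLUMNS if c not in cols]
    if missing:
        raise RppaFormatError(f"{source}: missing required columns {missing}")
    endpoints: list[RppaEndpoint] = []
    for i, row in enumerate(reader, start=2):
        printed = None
        if row.get("printed_ratio") not in (None, ""):
            printed = _parse_float(row["printed_ratio"], "printed_ratio", i)
        ep = RppaEndpoint(
            catalog_id=row["catalog_id"].strip(),
            antibody=row["antibody"].strip(),
            company=(row.get("company") or "").strip(),
            dilution=(row.get("dilution") or "").strip(),
            value_lOS=_parse_float(row["l_OS"], "l_OS", i),
            value_sOS=_parse_float(row["s_OS"], "s_OS", i),
            printed_ratio=printed,
        )
        if (
            printed is not None
            and ep.ratio_flag == FINITE
            and abs(ep.ratio - printed) > 0.005 + 1e-12
        ):
            log.warning(
                "%s line %d (%s): recomputed ratio %.4f != printed %.2f",
                source, i, ep.antibody, ep.ratio, printed,
            )
        endpoints.append(ep)
    return RppaTable(endpoints=endpoints)


def fixture_table() -> RppaTable:
    """The 51-endpoint two-patient panel shipped with the package."""
    text = resources.files("rppacra.data").joinpath("rppa_table1.csv").read_text("utf-8")
    return parse_rppa_table(text, source="rppa_table1.csv")


def select_divergent(table: RppaTable, fold: float = 2.0) -> DivergenceSelection:
    """Split endpoints at a symmetric fold threshold on the s-OS/l-OS ratio.

    ``ratio >= fold`` (and undefined-high) goes up, ``ratio <= 1/fold``
    (including exact zero) goes down.  The default 2-fold rule is the
    simple symmetric cut used to call differential activation on this panel.
    """
    if not fold > 1.0:
        raise ValueError(f"fold threshold must exceed 1, got {fold}")
    up, down = [], []
    for e in table:
        if e.ratio_flag == UNDEFINED_HIGH:
            up.append(e)
        elif e.ratio_flag == FINITE:
            if e.ratio >= fold:
                up.append(e)
            elif e.ratio <= 1.0 / fold:
                down.append(e)
    return DivergenceSelection(
        divergent_endpoints=up + down, up_in_sOS=up, down_in_sOS=down
    )


# --- antibody -> model-node mapping ---------------------------------------

@dataclass(frozen=True)
class MappingEntry:
    antibody: str
    node: str
    excluded: bool


def load_mapping(path: str | Path) -> dict[str, MappingEntry]:
    """Read an antibody->node mapping.

    CSV with columns ``antibody,node,excluded``, or YAML mapping
    ``antibody -> {node, excluded}`` (file suffix decides).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text) or {}
        return {
            ab: MappingEntry(antibody=ab, node=str(d.get("node") or ""),
                             excluded=bool(d.get("excluded", False)))
            for ab, d in raw.items()
        }
    return parse_mapping(text)


def parse_mapping(text: str) -> dict[str, MappingEntry]:
    reader = csv.DictReader(io.StringIO(text))
    cols = reader.fieldnames or []
    for c in ("antibody", "node", "excluded"):
        if c not in cols:
            raise RppaFormatError(f"mapping missing column {c!r}")
    out: dict[str, MappingEntry] = {}
    for row in reader:
        ab = row["antibody"].strip()
        out[ab] = MappingEntry(
            antibody=ab,
            node=row["node"].strip(),
            excluded=row["excluded"].strip().lower() in ("1", "true", "yes"),
        )
    return out


def fixture_mapping() -> dict[str, MappingEntry]:
    """Mapping from the shipped panel's antibodies onto the pathway nodes."""
    text = resources.files("rppacra.data").joinpath("antibody_map.csv").read_text("utf-8")
    return parse_mapping(text)


def _mapped_endpoints(
    table: RppaTable, mapping: Mapping[str, MappingEntry]
) -> list[tuple[RppaEndpoint, MappingEntry]]:
    pairs = []
    for e in table:
        if e.antibody not in mapping:
            raise MappingError(f"endpoint not covered by mapping: {e.antibody!r}")
        entry = mapping[e.antibody]
        if not entry.excluded:
            pairs.append((e, entry))
    return pairs


def aggregate_phosphosites(
    table: RppaTable, mapping: Mapping[str, MappingEntry]
) -> dict[str, dict]:
    """Per-node ratio summary: geometric mean of the finite positive ratios.

    Multiple phosphosite endpoints of one protein are combined on the log
    scale (geometric mean).  Endpoints without a finite positive ratio
    (zero numerator or denominator) cannot contribute a log-scale value;
    a node whose endpoints are all of that kind is flagged.
    """
    groups: dict[str, list[RppaEndpoint]] = {}
    for e, entry in _mapped_endpoints(table, mapping):
        groups.setdefault(entry.node, []).append(e)
    out: dict[str, dict] = {}
    for node, eps in groups.items():
        finite = sorted(
            e.ratio for e in eps if e.ratio_flag == FINITE and e.ratio > 0
        )  # sorted so the result is exactly row-order invariant
        if finite:
            ratio = math.exp(sum(math.log(r) for r in finite) / len(finite))
            flag = "ok"
        else:
            ratio, flag = math.nan, "no-finite-ratio"
        out[node] = {
            "ratio": ratio,
            "n_endpoints": len(eps),
            "n_finite": len(finite),
            "flag": flag,
        }
    return out


def select_calibration_proteins(
    table: RppaTable,
    model_nodes: Iterable[str],
    k_per_side: int = 2,
    mapping: Mapping[str, MappingEntry] | None = None,
) -> DivergenceSelection:
    """Choose the most divergent model proteins as calibration targets.

    Model-mapped endpoints are ranked by the signed divergence score
    (log2 ratio, with undefined-high / zero-ratio endpoints as the most
    extreme of their side), and the ``k_per_side`` most extreme *distinct*
    nodes on each side are taken: ``+`` for higher in s-OS, ``-`` for lower.
    """
    if k_per_side < 1:
        raise ValueError("k_per_side must be >= 1")
    if mapping is None:
        mapping = fixture_mapping()
    nodes = set(model_nodes)
    scored = [
        (e, mapping[e.antibody].node)
        for e, entry in _mapped_endpoints(table, mapping)
        if entry.node in nodes and not math.isnan(e.divergence_score)
    ]

    def pick(order: list[tuple[RppaEndpoint, str]], side: int) -> dict[str, int]:
        chosen: dict[str, int] = {}
        for e, node in order:
            score = e.divergence_score
            if side * score <= 0:  # requires strict divergence on this side
                break
            if node not in chosen:
                chosen[node] = side
            if len(chosen) == k_per_side:
                return chosen
        raise SelectionError(
            f"fewer than {k_per_side} divergent model-mapped proteins on "
            f"{'up' if side > 0 else 'down'} side"
        )

    up = pick(sorted(scored, key=lambda t: -t[0].divergence_score), +1)
    down = pick(sorted(scored, key=lambda t: t[0].divergence_score), -1)
    overlap = set(up) & set(down)
    if overlap:
        raise SelectionError(f"nodes selected on both sides: {sorted(overlap)}")
    up_eps = [e for e, n in scored if n in up and e.divergence_score > 0]
    down_eps = [e for e, n in scored if n in down and e.divergence_score < 0]
    return DivergenceSelection(
        divergent_endpoints=up_eps + down_eps,
        up_in_sOS=up_eps,
        down_in_sOS=down_eps,
        calibration_proteins={**up, **down},
    )
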