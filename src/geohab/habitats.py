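"""Habitat taxonomy, rule-based classification, weathering zonation and the
conservation-value engine.

The landform taxonomy is a four-level hierarchy (Category 1, coarsest, to
Category 4, finest) over seven groups: Mountains, Plains, Fluvial landform,
Coastal landform, Island, and the two special zones Baekdudaegan and DMZ. A
packaged transcription ships with the package; per-category type counts and
the parent structure are what the loader validates.

Conservation value grades a landform cell/unit I (absolute conservation),
II (transition) or III (coexistence with humans) from its landform grade,
human impact and geo-/biodiversity levels, by exact lookup in the packaged
13-row criteria table with a conservative completion policy for unprinted
combinations.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .raster_io import Grid, ensure_aligned

__all__ = [
    "LandformTaxonomy",
    "ClassificationRule",
    "load_taxonomy",
    "load_rules",
    "classify_cells",
    "load_peltier_zonation",
    "peltier_zone",
    "load_conservation_table",
    "conservation_value",
    "UNCLASSIFIED",
]

UNCLASSIFIED = 0  # reserved class code for cells no rule matched

GROUPS = [
    "Mountains", "Plains", "Fluvial landform", "Coastal landform",
    "Island", "Baekdudaegan", "DMZ",
]

_GRADES = ["I", "II", "III"]
_IMPACTS = ["None", "Moderate", "High"]
_LEVELS = ["Low", "Middle", "High"]


def _data_path(name: str):
    return importlib.resources.files("geohab.data").joinpath(name)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

@dataclass
class LandformTaxonomy:
    """Hierarchical type registry: (group, category, name, parent) entries."""

    entries: pd.DataFrame  # columns: group, category, name, parent
    text_category4_total: int | None = None  # total stated in prose, if any

    def counts(self) -> pd.DataFrame:
        """Per-(group, category) type counts in the layout of a count table."""
        tab = (self.entries.groupby(["group", "category"]).size()
               .unstack(fill_value=0))
        order = [g for g in GROUPS if g in tab.index]
        return tab.loc[order]

    def category_totals(self) -> dict[int, int]:
        return self.entries.groupby("category").size().to_dict()

    def types_in(self, group: str, category: int) -> list[str]:
        sel = (self.entries.group == group) & (self.entries.category == category)
        return self.entries.loc[sel, "name"].tolist()


def load_taxonomy(path=None) -> LandformTaxonomy:
    """Load the landform taxonomy from YAML (packaged fixture by default).

    Validates the hierarchy: exactly one Category-1 type per group, and
    every Category k>1 type names a Category k-1 parent that exists in its
    group; an orphan raises. The loader reports both category-4 totals
    where the source states two (row total vs prose total).
    """
    if path is None:
        with _data_path("taxonomy.yml").open() as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    if not doc or "groups" not in doc or not doc["groups"]:
        raise ValueError("empty or malformed taxonomy file")
    rows = []
    for group, levels in doc["groups"].items():
        for cat in (1, 2, 3, 4):
            for entry in levels.get(f"category{cat}", []):
                if isinstance(entry, str):
                    entry = {"name": entry, "parent": None}
                rows.append({"group": group, "category": cat,
                             "name": entry["name"],
                             "parent": entry.get("parent")})
    entries = pd.DataFrame(rows)
    for group, sub in entries.groupby("group"):
        c1 = sub[sub.category == 1]
        if len(c1) != 1:
            raise ValueError(
                f"group {group!r} must have exactly one Category-1 type")
        for cat in (2, 3, 4):
            parents = set(sub.loc[sub.category == cat - 1, "name"])
            for _, row in sub[sub.category == cat].iterrows():
                parent = row["parent"] or (c1.iloc[0]["name"] if cat == 2
                                           else None)
                if parent not in parents:
                    raise ValueError(
                        f"orphan type {row['name']!r} (group {group}, "
                        f"category {cat}): parent {parent!r} not found at "
                        f"category {cat - 1}")
    return LandformTaxonomy(entries,
                            text_category4_total=doc.get("text_category4_total"))


# ---------------------------------------------------------------------------
# rule-based cell classification
# ---------------------------------------------------------------------------

_OPS = {
    "lt": np.less, "le": np.less_equal, "gt": np.greater,
    "ge": np.greater_equal, "eq": np.equal, "ne": np.not_equal,
}


@dataclass
class ClassificationRule:
    """Conjunction of layer predicates mapping matched cells to a type.

    ``conditions`` is a list of ``{layer, op, value}`` (ops lt/le/gt/ge/
    eq/ne/in/between). Higher ``priority`` wins on contested cells;
    priorities must be unique across a rule set.
    """

    type_name: str
    code: int
    priority: int
    conditions: list[dict] = field(default_factory=list)

    def evaluate(self, layers: dict[str, Grid]) -> np.ndarray:
        ref = next(iter(layers.values()))
        out = np.ones(ref.shape, dtype=bool)
        for cond in self.conditions:
            lname = cond["layer"]
            if lname not in layers:
                raise KeyError(
                    f"rule {self.type_name!r} references missing layer "
                    f"{lname!r}")
            vals = layers[lname].values
            op = cond["op"]
            if op == "in":
                out &= np.isin(vals, cond["value"])
            elif op == "between":
                lo, hi = cond["value"]
                out &= (vals >= lo) & (vals <= hi)
            elif op in _OPS:
                out &= _OPS[op](vals, cond["value"])
            else:
                raise ValueError(f"unknown rule op {op!r}")
            out &= layers[lname].mask()
        return out


def load_rules(path=None) -> list[ClassificationRule]:
    """Load classification rules from YAML (packaged defaults otherwise)."""
    if path is None:
        with _data_path("default_rules.yml").open() as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    rules = [ClassificationRule(r["type_name"], int(r["code"]),
                                int(r["priority"]), r.get("conditions", []))
             for r in doc["rules"]]
    prios = [r.priority for r in rules]
    if len(set(prios)) != len(prios):
        raise ValueError("rule priorities must be unique")
    return rules


def classify_cells(layers: dict[str, Grid],
                   rules: list[ClassificationRule]) -> Grid:
    """Assign every valid cell the highest-priority matching rule's code.

    Cells no rule matches get ``UNCLASSIFIED`` (0), never silent nodata, so
    classified + unclassified always partition the valid area.
    """
    if not rules:
        raise ValueError("at least one classification rule is required")
    ensure_aligned(*layers.values(), context="classify_cells")
    ref = next(iter(layers.values()))
    out = np.full(ref.shape, float(UNCLASSIFIED))
    for rule in sorted(rules, key=lambda r: r.priority):
        hit = rule.evaluate(layers)
        out[hit] = rule.code
    valid = np.ones(ref.shape, dtype=bool)
    for g in layers.values():
        valid &= g.mask()
    return ref.like(np.where(valid, out, ref.nodata))


# ---------------------------------------------------------------------------
# Peltier weathering zonation
# ---------------------------------------------------------------------------

def load_peltier_zonation(path=None) -> list[dict]:
    """Load the weathering-regions diagram: labeled rectangles in
    (mean annual temperature degC, annual precipitation mm) space.

    The packaged digitization partitions the configured climate envelope;
    regions are half-open on their upper edges except at the envelope
    boundary, so each (T, P) point falls in exactly one region.
    """
    if path is None:
        with _data_path("peltier.yml").open() as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    return doc["regions"]


def peltier_zone(temperature: Grid, precipitation: Grid,
                 regions: list[dict] | None = None) -> tuple[Grid, dict]:
    """Label each cell's weathering regime from its (T, P) pair.

    Returns the coded label grid and the code -> label legend (code 0 is
    ``out_of_envelope`` for (T, P) outside every configured region).
    """
    regions = regions if regions is not None else load_peltier_zonation()
    ensure_aligned(temperature, precipitation, context="peltier_zone")
    labels = ["out_of_envelope"] + [r["label"] for r in regions]
    legend = {i: lab for i, lab in enumerate(dict.fromkeys(labels))}
    code_of = {lab: i for i, lab in legend.items()}
    t, p = temperature.values, precipitation.values
    out = np.zeros(temperature.shape)
    assigned = np.zeros(temperature.shape, dtype=bool)
    for r in regions:
        hi_t = (t <= r["t_max"]) if r.get("t_max_closed") else (t < r["t_max"])
        hi_p = (p <= r["p_max"]) if r.get("p_max_closed") else (p < r["p_max"])
        sel = (~assigned & (t >= r["t_min"]) & hi_t
               & (p >= r["p_min"]) & hi_p)
        out[sel] = code_of[r["label"]]
        assigned |= sel
    valid = temperature.mask() & precipitation.mask()
    out = np.where(valid, out, temperature.nodata)
    return temperature.like(out), legend


# ---------------------------------------------------------------------------
# conservation-value engine
# ---------------------------------------------------------------------------

def load_conservation_table(path=None) -> pd.DataFrame:
    """Load the 13-row conservation-criteria table (packaged by default)."""
    # keep_default_na: the impact level "None" is a category, not missing
    if path is None:
        with _data_path("conservation_table.csv").open() as fh:
            table = pd.read_csv(fh, keep_default_na=False)
    else:
        table = pd.read_csv(path, keep_default_na=False)
    expected = {"landform_grade", "human_impact", "geodiversity",
                "biodiversity", "value"}
    if set(table.columns) != expected:
        raise ValueError(f"conservation table must have columns {expected}")
    return table


def conservation_value(
    landform_grade: str,
    human_impact: str,
    geodiversity: str,
    biodiversity: str,
    table: pd.DataFrame | None = None,
) -> tuple[str, bool]:
    """Grade a landform unit I, II or III.

    Exact lookup against the criteria table; combinations the table does
    not print are resolved conservatively: among printed rows with the same
    grade and impact whose diversity levels are each <= the query's, take
    the worst (highest-numbered) value, falling back to same-grade rows and
    finally to III. Returns ``(value, extrapolated)`` — ``extrapolated`` is
    False only for printed rows.
    """
    for val, dom, what in ((landform_grade, _GRADES, "landform_grade"),
                           (human_impact, _IMPACTS, "human_impact"),
                           (geodiversity, _LEVELS, "geodiversity"),
                           (biodiversity, _LEVELS, "biodiversity")):
        if val not in dom:
            raise ValueError(f"{what} must be one of {dom}, got {val!r}")
    table = table if table is not None else load_conservation_table()
    exact = table[
        (table.landform_grade == landform_grade)
        & (table.human_impact == human_impact)
        & (table.geodiversity == geodiversity)
        & (table.biodiversity == biodiversity)
    ]
    if len(exact):
        return str(exact.iloc[0]["value"]), False
    rank = {lev: i for i, lev in enumerate(_LEVELS)}
    sub = table[(table.landform_grade == landform_grade)
                & (table.human_impact == human_impact)]
    dominated = sub[
        sub.geodiversity.map(rank).le(rank[geodiversity])
        & sub.biodiversity.map(rank).le(rank[biodiversity])
    ]
    pool = dominated if len(dominated) else sub
    if len(pool):
        worst = max(pool["value"], key=_GRADES.index)
        return worst, True
    return "III", True
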