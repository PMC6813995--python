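"""Per-gene, per-species 'root-to-tip' dN/dS from branch-wise rate estimates.

Branch-wise dN and dS come either from codeml free-ratio (model=1) main
output files, one per gene, or from a long-format CSV.  Each branch is
identified by the set of tip labels descending from its child node, which
makes records portable between the numbering codeml uses internally and the
species tree the downstream statistics run on.

The root-to-tip statistic accumulates rates along the path from the most
recent common ancestor of the retained species to a tip.  Two constructions
are supported:

``path_ratio`` (default)
    sum of dN over the path divided by sum of dS over the path — robust to
    individual branches with near-zero dS, since the sums absorb them.

``mean_branch_omega``
    arithmetic mean of the per-branch dN/dS values on the path; undefined
    (missing) whenever any branch on the path has dS below ``DS_FLOOR``.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError
from .phylo import PhyloTree, normalize_label

__all__ = [
    "BranchRate",
    "BranchRates",
    "parse_freeratio_output",
    "read_rates_csv",
    "root_to_tip",
    "build_rate_table",
    "DS_FLOOR",
]

#: dS below this invalidates a branch's per-branch omega (mean_branch_omega
#: mode); the branch still contributes its dN and dS to path sums.
DS_FLOOR = 1e-6


@dataclass(frozen=True)
class BranchRate:
    """Rates on one branch, identified by its child clade's tip-label set."""

    clade: frozenset[str]
    dn: float
    ds: float
    omega: float  # as reported; NaN when dS ~ 0 made it unreliable

    @property
    def omega_reliable(self) -> bool:
        return self.ds > DS_FLOOR and math.isfinite(self.omega)


@dataclass
class BranchRates:
    """All branch records for one gene."""

    gene_id: str
    records: dict[frozenset[str], BranchRate] = field(default_factory=dict)

    def add(self, rec: BranchRate):
        if rec.clade in self.records:
            raise InvalidInputError(
                f"{self.gene_id}: duplicate branch record for clade {sorted(rec.clade)}"
            )
        if rec.dn < 0 or rec.ds < 0:
            raise InvalidInputError(f"{self.gene_id}: negative dN or dS")
        self.records[rec.clade] = rec

    def __len__(self):
        return len(self.records)


# ---------------------------------------------------------------------------
# codeml free-ratio parsing
# ---------------------------------------------------------------------------

_BRANCH_ROW = re.compile(
    r"^\s*(\d+)\.\.(\d+)\s+((?:[-\d.eE+]+\s+)+[-\d.eE+]+)\s*$"
)
_NAME = re.compile(r"[A-Za-z_][A-Za-z0-9_.\-]*")


def parse_freeratio_output(text: str, gene_id: str = "gene") -> BranchRates:
    """Parse a codeml free-ratio (model=1) main result file.

    Expects, in order: a ``TREE #`` line with the numeric topology, a
    parenthesized tree carrying the taxon names in the same order, and the
    ``dN & dS for each branch`` table whose rows look like::

        6..7      0.081  935.1  318.9  0.1106  0.0066  0.0594

    with columns t, N, S, dN/dS, dN, dS (extra trailing columns are
    ignored).  Branch identity is resolved by rebuilding the parent/child
    graph from the branch rows and mapping tip numbers 1..n onto the names
    tree's taxa in order of appearance.
    """
    lines = text.splitlines()

    tree_i = next(
        (i for i, l in enumerate(lines) if re.match(r"^TREE\s*#", l)), None
    )
    if tree_i is None:
        raise ParseError(f"{gene_id}: no 'TREE #' line found")

    names: list[str] | None = None
    for line in lines[tree_i + 1 :]:
        s = line.strip()
        if s.startswith("(") and _NAME.search(s):
            names = [normalize_label(m) for m in _NAME.findall(s)]
            break
    if not names:
        raise ParseError(f"{gene_id}: no taxon-name tree found after TREE # line")

    table_i = next(
        (i for i, l in enumerate(lines) if "dN & dS for each branch" in l), None
    )
    if table_i is None:
        raise ParseError(f"{gene_id}: branch table ('dN & dS for each branch') missing")

    rows = []
    for line in lines[table_i + 1 :]:
        m = _BRANCH_ROW.match(line)
        if m:
            vals = m.group(3).split()
            if len(vals) < 6:
                raise ParseError(f"{gene_id}: branch row has too few columns: {line!r}")
            rows.append((int(m.group(1)), int(m.group(2)), [float(v) for v in vals]))
        elif rows and line.strip() and not set(line.strip()) <= set("-= "):
            break  # past the table
    if not rows:
        raise ParseError(f"{gene_id}: branch table contains no branch rows")

    n = len(names)
    children: dict[int, list[int]] = {}
    for parent, child, _ in rows:
        children.setdefault(parent, []).append(child)
    tip_nums = {c for _, c, _ in rows if c <= n}
    if tip_nums != set(range(1, n + 1)):
        raise ParseError(
            f"{gene_id}: branch rows cover tips {sorted(tip_nums)} but the tree "
            f"names {n} taxa"
        )

    def tipset(node: int, _seen=None) -> frozenset[str]:
        if node <= n:
            return frozenset([names[node - 1]])
        out: set[str] = set()
        for c in children.get(node, []):
            out |= tipset(c)
        if not out:
            raise ParseError(f"{gene_id}: internal node {node} has no descendants")
        return frozenset(out)

    rates = BranchRates(gene_id=gene_id)
    for parent, child, vals in rows:
        _t, _N, _S, omega, dn, ds = vals[:6]
        if ds <= DS_FLOOR:
            omega = float("nan")
        rates.add(BranchRate(clade=tipset(child), dn=dn, ds=ds, omega=omega))
    return rates


def read_rates_csv(path_or_buf, tree: PhyloTree | None = None) -> dict[str, BranchRates]:
    """Read long-format branch rates: columns gene, child, dN, dS[, omega].

    ``child`` names the branch by its child node: a tip label, an internal
    node label present in ``tree``, or a ``|``-joined list of tip labels.
    A ``parent`` column, if present, is ignored (branch identity is fully
    determined by the child clade).
    """
    df = pd.read_csv(path_or_buf)
    need = {"gene", "child", "dN", "dS"}
    if not need <= set(df.columns):
        raise ParseError(f"rates CSV must have columns {sorted(need)}")
    label_map: dict[str, frozenset[str]] = {}
    if tree is not None:
        for clade, node in tree.clade_tipsets().items():
            if node.is_leaf():
                label_map[next(iter(clade))] = clade
            elif node.label:
                label_map[normalize_label(node.label)] = clade

    out: dict[str, BranchRates] = {}
    for _, row in df.iterrows():
        gene = str(row["gene"])
        child = normalize_label(str(row["child"]))
        if "|" in child:
            clade = frozenset(normalize_label(p) for p in child.split("|"))
        elif child in label_map:
            clade = label_map[child]
        else:
            clade = frozenset([child])
        ds = float(row["dS"])
        omega = float(row["omega"]) if "omega" in df.columns and pd.notna(row.get("omega")) else (
            float(row["dN"]) / ds if ds > DS_FLOOR else float("nan")
        )
        if ds <= DS_FLOOR:
            omega = float("nan")
        out.setdefault(gene, BranchRates(gene_id=gene)).add(
            BranchRate(clade=clade, dn=float(row["dN"]), ds=ds, omega=omega)
        )
    return out


# ---------------------------------------------------------------------------
# root-to-tip statistic
# ---------------------------------------------------------------------------


def root_to_tip(
    rates: BranchRates, tree: PhyloTree, tip: str, mode: str = "path_ratio"
) -> float:
    """Root-to-tip dN/dS for one tip; NaN when undefined (with a warning).

    The path runs from the tree's root (the MRCA of its current tips — prune
    first if species were dropped) to ``tip``.  Every branch on the path must
    have a rate record; otherwise the value is missing.
    """
    if mode not in ("path_ratio", "mean_branch_omega"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    path = tree.path_to_tip(tip)
    recs = []
    for clade in path:
        rec = rates.records.get(clade)
        if rec is None:
            warnings.warn(
                f"{rates.gene_id}/{tip}: no rate record for branch {sorted(clade)}; "
                "value set to missing",
                stacklevel=2,
            )
            return float("nan")
        recs.append(rec)
    if mode == "path_ratio":
        ds_sum = sum(r.ds for r in recs)
        if ds_sum <= DS_FLOOR:
            warnings.warn(
                f"{rates.gene_id}/{tip}: path dS sum ~ 0, ratio undefined",
                stacklevel=2,
            )
            return float("nan")
        return sum(r.dn for r in recs) / ds_sum
    # mean_branch_omega: any unreliable branch omega poisons the mean
    if not all(r.omega_reliable for r in recs):
        warnings.warn(
            f"{rates.gene_id}/{tip}: branch with dS ~ 0 on path, "
            "mean_branch_omega undefined",
            stacklevel=2,
        )
        return float("nan")
    return float(np.mean([r.omega for r in recs]))


def build_rate_table(
    rate_sets, tree: PhyloTree, mode: str = "path_ratio"
) -> pd.DataFrame:
    """Gene x species matrix of root-to-tip dN/dS.

    ``rate_sets`` is an iterable of :class:`BranchRates` (or a mapping whose
    values are).  Per-cell failures become NaN; an empty collection yields an
    empty table with a warning.
    """
    if hasattr(rate_sets, "values"):
        rate_sets = list(rate_sets.values())
    else:
        rate_sets = list(rate_sets)
    genes = [r.gene_id for r in rate_sets]
    if len(set(genes)) != len(genes):
        raise InvalidInputError("gene ids must be unique")
    if not rate_sets:
        warnings.warn("empty gene collection; returning empty table", stacklevel=2)
        return pd.DataFrame(columns=tree.tip_labels)
    rows = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rs in rate_sets:
            rows[rs.gene_id] = {
                tip: root_to_tip(rs, tree, tip, mode=mode) for tip in tree.tip_labels
            }
    return pd.DataFrame.from_dict(rows, orient="index")[tree.tip_labels]
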