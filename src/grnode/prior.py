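"""Prior knowledge about network connections.

Knowledge about stimulus->gene and gene->gene connections enters in two
modes:

* **fix** - rigid structural requirements.  Code 1/10/-10 entries are always
  part of the inferred structure (10 activation, -10 inhibition constrain the
  coefficient sign); code 0 is a hard exclusion: the connection is never
  offered to the structure search.
* **flexible** - soft knowledge.  Disagreement between the inferred structure
  and a flexible entry adds a score-weighted sign-distance term to the
  objective, weighted overall by lambda.

Connection codes: ``0`` no connection, ``1`` connection of unknown sign,
``10`` activation, ``-10`` inhibition; entries without knowledge are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PriorFormatError

__all__ = [
    "PriorKnowledge",
    "encode_edge",
    "sign_distance",
    "classify_edges",
    "CODES",
]

CODES = (0.0, 1.0, 10.0, -10.0)

#: origin tag that earns the dedicated edge colour for predicted binding sites
BINDING_SITE_ORIGIN = "binding_site"


def encode_edge(coefficient: float, tol: float = 1e-6) -> int:
    """Convert a model coefficient into the connection-code notation.

    ``0`` within the zero tolerance, ``10`` activation, ``-10`` inhibition.
    The presence-only code ``1`` is an input notation and never produced.
    """
    c = float(coefficient)
    if abs(c) <= tol:
        return 0
    return 10 if c > 0 else -10


def sign_distance(model_code: int, prior_code: float) -> int:
    """Binary disagreement d between a model edge code and a prior code.

    0 when compatible: exact code match, presence-only prior (1) matched by
    any present edge, or no prior knowledge (NaN).  1 otherwise (edge /
    no-edge mismatch or sign flip).
    """
    if prior_code is None or (isinstance(prior_code, float) and np.isnan(prior_code)):
        return 0
    p = float(prior_code)
    m = int(model_code)
    if p == 1.0:
        return 0 if m in (10, -10) else 1
    if p == 0.0:
        return 0 if m == 0 else 1
    if p in (10.0, -10.0):
        return 0 if m == p else 1
    raise PriorFormatError(f"invalid prior code {prior_code!r}")


@dataclass
class PriorKnowledge:
    """Fix/flexible connection-code matrices with reliability scores.

    ``A_*`` matrices are N x N (target gene x source gene), ``B_*`` are
    N x M (target gene x stimulus); NaN marks absent knowledge.  ``S_A`` and
    ``S_B`` hold reliability scores in [0, 1] for flexible entries.  ``lam``
    is the penalty weight; ``None`` defers to the configuration value.
    ``origin_A``/``origin_B`` tag the provenance of each entry (e.g.
    ``"literature"`` or ``"binding_site"``) for the graph colour code.
    """

    gene_names: list[str]
    input_names: list[str]
    A_fix: np.ndarray = None  # type: ignore[assignment]
    B_fix: np.ndarray = None  # type: ignore[assignment]
    A_flex: np.ndarray = None  # type: ignore[assignment]
    B_flex: np.ndarray = None  # type: ignore[assignment]
    S_A: np.ndarray = None  # type: ignore[assignment]
    S_B: np.ndarray = None  # type: ignore[assignment]
    lam: float | None = None
    origin_A: np.ndarray = None  # type: ignore[assignment]
    origin_B: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n, m = len(self.gene_names), len(self.input_names)
        for name, shape in (("A_fix", (n, n)), ("B_fix", (n, m)),
                            ("A_flex", (n, n)), ("B_flex", (n, m)),
                            ("S_A", (n, n)), ("S_B", (n, m))):
            v = getattr(self, name)
            if v is None:
                v = np.full(shape, np.nan)
            v = np.asarray(v, dtype=float)
            if v.shape != shape:
                raise PriorFormatError(f"{name} must have shape {shape}")
            setattr(self, name, v)
        for name, shape in (("origin_A", (n, n)), ("origin_B", (n, m))):
            v = getattr(self, name)
            if v is None:
                v = np.full(shape, None, dtype=object)
            setattr(self, name, np.asarray(v, dtype=object))
        self.validate()

    @classmethod
    def empty(cls, gene_names, input_names, lam: float | None = None):
        return cls(list(gene_names), list(input_names), lam=lam)

    def validate(self) -> None:
        for mat in (self.A_fix, self.B_fix, self.A_flex, self.B_flex):
            vals = mat[~np.isnan(mat)]
            bad = set(np.unique(vals)) - set(CODES)
            if bad:
                raise PriorFormatError(f"invalid prior code(s) {sorted(bad)}")
        if np.any(~np.isnan(self.A_fix) & ~np.isnan(self.A_flex)) or np.any(
            ~np.isnan(self.B_fix) & ~np.isnan(self.B_flex)
        ):
            raise PriorFormatError("fix and flexible set for the same entry")
        for flex, s, label in ((self.A_flex, self.S_A, "S_A"),
                               (self.B_flex, self.S_B, "S_B")):
            has_flex = ~np.isnan(flex)
            missing = has_flex & np.isnan(s)
            # default missing scores to full reliability
            s[missing] = 1.0
            present = s[~np.isnan(s)]
            if np.any((present < 0) | (present > 1)):
                raise PriorFormatError(f"{label} scores must lie in [0, 1]")

    @property
    def is_empty(self) -> bool:
        return all(
            np.all(np.isnan(m))
            for m in (self.A_fix, self.B_fix, self.A_flex, self.B_flex)
        )

    # ------------------------------------------------- structural contracts
    def fix_gene_sources(self, gene: int) -> list[int]:
        """Gene sources whose fix code forces an edge into sub-model ``gene``."""
        row = self.A_fix[gene]
        return [j for j in range(len(row))
                if not np.isnan(row[j]) and row[j] != 0.0]

    def fix_input_sources(self, gene: int) -> list[int]:
        row = self.B_fix[gene]
        return [m for m in range(len(row))
                if not np.isnan(row[m]) and row[m] != 0.0]

    def excluded_gene_sources(self, gene: int) -> set[int]:
        """Gene sources forbidden by a fix code 0 (hard exclusion)."""
        row = self.A_fix[gene]
        return {j for j in range(len(row)) if row[j] == 0.0}

    def excluded_input_sources(self, gene: int) -> set[int]:
        row = self.B_fix[gene]
        return {m for m in range(len(row)) if row[m] == 0.0}

    def sign_interval(self, code: float, bound: float, floor: float = 1e-5):
        """Coefficient box implied by a fix code (10 / -10 constrain the sign).

        The magnitude floor sits above the edge-code zero tolerance so a
        sign-constrained fix connection always encodes as present.
        """
        if code == 10.0:
            return (floor, bound)
        if code == -10.0:
            return (-bound, -floor)
        return (-bound, bound)

    # ------------------------------------------------------------- penalty
    def penalty_row(self, gene: int, gene_coeffs: dict, input_coeffs: dict,
                    tol: float = 1e-6) -> float:
        """Score-weighted sign-distance sum of sub-model ``gene``'s row.

        ``gene_coeffs``/``input_coeffs`` map source index to coefficient;
        sources absent from the maps count as coefficient 0.  Every position
        carrying a flexible entry contributes s * d; fix entries are enforced
        structurally and carry no penalty.  The caller multiplies by lambda.
        """
        total = 0.0
        for j in range(len(self.gene_names)):
            p = self.A_flex[gene, j]
            if np.isnan(p):
                continue
            code = encode_edge(gene_coeffs.get(j, 0.0), tol)
            total += self.S_A[gene, j] * sign_distance(code, p)
        for m in range(len(self.input_names)):
            p = self.B_flex[gene, m]
            if np.isnan(p):
                continue
            code = encode_edge(input_coeffs.get(m, 0.0), tol)
            total += self.S_B[gene, m] * sign_distance(code, p)
        return total

    # ----------------------------------------------------------------- I/O
    @classmethod
    def from_csv(cls, path, gene_names, input_names, lam: float | None = None):
        """Read a long-form prior table.

        Columns: ``source, target, mode, code[, score, origin]`` with mode
        ``fix`` or ``flexible``.  ``source`` may be a gene or stimulus name,
        ``target`` must be a gene name.
        """
        df = pd.read_csv(path)
        required = {"source", "target", "mode", "code"}
        if not required.issubset(df.columns):
            raise PriorFormatError(
                f"prior table needs columns {sorted(required)}"
            )
        pk = cls.empty(gene_names, input_names, lam=lam)
        for _, row in df.iterrows():
            src, dst, mode = str(row["source"]), str(row["target"]), str(row["mode"])
            code = float(row["code"])
            if code not in CODES:
                raise PriorFormatError(f"invalid code {code} for {src}->{dst}")
            if dst not in gene_names:
                raise PriorFormatError(f"unknown target gene {dst!r}")
            i = gene_names.index(dst)
            score = float(row.get("score", np.nan)) if "score" in df.columns else np.nan
            origin = str(row["origin"]) if "origin" in df.columns and not pd.isna(row.get("origin")) else None
            if src in input_names:
                m = input_names.index(src)
                if mode == "fix":
                    pk.B_fix[i, m] = code
                elif mode == "flexible":
                    pk.B_flex[i, m] = code
                    pk.S_B[i, m] = score
                else:
                    raise PriorFormatError(f"invalid mode {mode!r}")
                pk.origin_B[i, m] = origin
            elif src in gene_names:
                j = gene_names.index(src)
                if mode == "fix":
                    pk.A_fix[i, j] = code
                elif mode == "flexible":
                    pk.A_flex[i, j] = code
                    pk.S_A[i, j] = score
                else:
                    raise PriorFormatError(f"invalid mode {mode!r}")
                pk.origin_A[i, j] = origin
            else:
                raise PriorFormatError(f"unknown source {src!r}")
        pk.validate()
        return pk


def _prior_code(prior: PriorKnowledge, kind: str, i: int, j: int):
    """Fix or flexible code at a position (at most one is set)."""
    fix = prior.A_fix[i, j] if kind == "gene" else prior.B_fix[i, j]
    if not np.isnan(fix):
        return fix, "fix"
    flex = prior.A_flex[i, j] if kind == "gene" else prior.B_flex[i, j]
    if not np.isnan(flex):
        return flex, "flexible"
    return None, None


def classify_edges(model, prior: PriorKnowledge | None, tol: float = 1e-6):
    """Colour every inferred edge and unreproduced prior entry.

    Returns a list of dicts with keys ``source, target, kind, code, colour,
    style``.  Colours: ``black`` inferred without knowledge, ``green``
    agreement, ``red`` contradiction (wrong sign or prior "no connection"),
    ``blue`` agreement supported by a predicted binding site, ``grey``
    (dashed) prior connection absent from the model.
    """
    records = []
    genes, inputs = model.gene_names, model.input_names
    for i, tgt in enumerate(genes):
        sources = [("input", m, name) for m, name in enumerate(inputs)]
        sources += [("gene", j, name) for j, name in enumerate(genes)]
        for kind, j, src in sources:
            coeff = model.edge_coefficient(src, tgt)
            code = encode_edge(coeff, tol)
            pcode, porigin = (None, None)
            origin = None
            if prior is not None:
                ii = prior.gene_names.index(tgt)
                jj = (prior.input_names.index(src) if kind == "input"
                      else prior.gene_names.index(src))
                pcode, _mode = _prior_code(prior, kind, ii, jj)
                origin = (prior.origin_B[ii, jj] if kind == "input"
                          else prior.origin_A[ii, jj])
            if code != 0:
                if pcode is None:
                    colour = "black"
                elif sign_distance(code, pcode) == 0 and pcode != 0.0:
                    colour = "blue" if origin == BINDING_SITE_ORIGIN else "green"
                else:
                    colour = "red"
                records.append(dict(source=src, target=tgt, kind=kind,
                                    code=code, colour=colour, style="solid"))
            elif pcode is not None and pcode not in (0.0,):
                records.append(dict(source=src, target=tgt, kind=kind,
                                    code=0, colour="grey", style="dashed"))
    return records
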