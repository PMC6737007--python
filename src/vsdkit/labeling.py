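"""Combinatorial selective isotope labeling (CSL) design for NMR backbone assignment.

In CSL, several protein samples are produced in which each amino-acid *type*
carries one of four labeling types:

* ``X`` — unlabeled,
* ``N`` — 15N only,
* ``C`` — 13C' (carbonyl) only,
* ``D`` — uniformly 13C,15N (carries 15N, 13C' and 13CA).

An amide cross peak of residue *i* appears in a 2D 1H,15N spectrum only when
residue *i* is 15N-labeled (and is not a proline).  The 2D planes of HNCO and
HNCA then report whether the *preceding* residue carries 13C' and/or 13CA.
The per-sample presence pattern of (NH, NH+HNCO, NH+HNCA) peaks therefore
encodes the (previous, current) residue-type pair; if a residue's pattern is
unique along the sequence, its cross peak is assigned without any 3D
experiment.  This module designs such schemes, predicts the resulting
spectra, and reports the attainable assignment coverage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "LabelingType",
    "LabelingStock",
    "LabelingScheme",
    "AssignmentTable",
    "UnknownResidueTypeError",
    "encode_pair",
    "assignment_table",
    "design_scheme",
    "predict_spectra",
    "read_fasta_sequence",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: PairCode symbols: 0 no NH peak, 1 NH only, 2 NH+HNCO, 3 NH+HNCA, 4 NH+both.
SYMBOLS = (0, 1, 2, 3, 4)


class UnknownResidueTypeError(ValueError):
    """An amino-acid token outside the one-letter alphabet (or the scheme)."""


class LabelingType(Enum):
    """One of the four constructible labeling types.

    The enum closes the type universe: no other flag combination exists.
    """

    X = ("X", False, False, False)
    N = ("N", True, False, False)
    C = ("C", False, True, False)
    D = ("D", True, True, True)

    def __init__(self, token: str, has15n: bool, has13co: bool, has13ca: bool):
        self.token = token
        self.has15N = has15n
        self.has13CO = has13co
        self.has13CA = has13ca

    @classmethod
    def from_token(cls, token: str) -> "LabelingType":
        try:
            return cls[token]
        except KeyError:
            raise UnknownResidueTypeError(f"unknown labeling token {token!r}") from None


# Canonical token order used for deterministic lexicographic tie-breaking.
TOKEN_ORDER = {t: i for i, t in enumerate("XNCD")}


@dataclass(frozen=True)
class LabelingStock:
    """Available labeling types (and optional prices) per amino-acid type.

    ``availability`` maps a one-letter amino-acid code to the set of tokens
    that can be purchased for it; ``X`` (unlabeled) is always available and is
    added implicitly.  ``prices`` maps (amino acid, token) to a non-negative
    price per sample; missing entries cost 0 (``X`` is free by default).
    """

    availability: Mapping[str, frozenset]
    prices: Mapping[tuple, float] = field(default_factory=dict)

    def __post_init__(self):
        avail = {}
        for aa, tokens in dict(self.availability).items():
            if aa not in AMINO_ACIDS:
                raise UnknownResidueTypeError(f"unknown amino acid {aa!r} in stock")
            toks = frozenset(tokens) | {"X"}
            for t in toks:
                LabelingType.from_token(t)
            avail[aa] = toks
        object.__setattr__(self, "availability", avail)
        for key, p in self.prices.items():
            if p < 0:
                raise ValueError(f"negative price for {key}")

    @classmethod
    def uniform(cls, aas: Iterable[str] = AMINO_ACIDS,
                tokens: Iterable[str] = "XNCD") -> "LabelingStock":
        toks = frozenset(tokens)
        return cls({aa: toks for aa in aas})

    def tokens_for(self, aa: str) -> frozenset:
        if aa not in self.availability:
            # Unlisted types can always be left unlabeled.
            return frozenset({"X"})
        return self.availability[aa]

    def price_of(self, aa: str, token: str) -> float:
        return float(self.prices.get((aa, token), 0.0))


@dataclass(frozen=True)
class LabelingScheme:
    """Per-sample, per-amino-acid-type labeling assignment.

    ``assignment`` maps one-letter amino-acid codes to a tuple of
    :class:`LabelingType`, one entry per sample (so all tuples share the
    length ``n_samples``).
    """

    assignment: Mapping[str, tuple]

    def __post_init__(self):
        assign = {}
        lengths = set()
        for aa, types in dict(self.assignment).items():
            if aa not in AMINO_ACIDS:
                raise UnknownResidueTypeError(f"unknown amino acid {aa!r}")
            types = tuple(
                t if isinstance(t, LabelingType) else LabelingType.from_token(t)
                for t in types
            )
            lengths.add(len(types))
            assign[aa] = types
        if not assign or lengths != {next(iter(lengths))} or next(iter(lengths)) < 1:
            raise ValueError("all amino-acid types need the same n_samples >= 1")
        object.__setattr__(self, "assignment", assign)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.assignment.values())))

    @property
    def amino_acids(self) -> tuple:
        return tuple(sorted(self.assignment))

    def types_for(self, aa: str) -> tuple:
        try:
            return self.assignment[aa]
        except KeyError:
            raise UnknownResidueTypeError(
                f"amino acid {aa!r} not covered by the scheme"
            ) from None

    def total_price(self, stock: LabelingStock) -> float:
        return sum(
            stock.price_of(aa, t.token)
            for aa, types in self.assignment.items()
            for t in types
        )

    def validate_against(self, stock: LabelingStock) -> None:
        for aa, types in self.assignment.items():
            allowed = stock.tokens_for(aa)
            for t in types:
                if t.token not in allowed:
                    raise ValueError(
                        f"token {t.token} for {aa} is not in the stock"
                    )

    # --- CSV layout mirroring the usual scheme tables: rows = samples ---
    def to_frame(self) -> pd.DataFrame:
        aas = self.amino_acids
        data = {aa: [t.token for t in self.assignment[aa]] for aa in aas}
        return pd.DataFrame(data, index=[f"S{i + 1}" for i in range(self.n_samples)])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="sample")

    @classmethod
    def from_csv(cls, path) -> "LabelingScheme":
        df = pd.read_csv(path, index_col=0)
        return cls({aa: tuple(df[aa]) for aa in df.columns})

    def _lex_key(self):
        return tuple(
            TOKEN_ORDER[t.token] for aa in self.amino_acids for t in self.assignment[aa]
        )


def _pair_symbol(prev: LabelingType | None, curr: LabelingType, curr_is_pro: bool) -> int:
    if curr_is_pro or not curr.has15N:
        return 0
    hnco = prev is not None and prev.has13CO
    hnca = prev is not None and prev.has13CA
    return 1 + (1 if hnco else 0) + (2 if hnca else 0)


def encode_pair(scheme: LabelingScheme, prev_aa: str | None, curr_aa: str) -> tuple:
    """Per-sample spectral code for a sequential residue pair.

    ``prev_aa`` may be ``None`` (sequence start): the residue then carries no
    sequential 13C information, so only symbols 0/1 can occur.
    """
    if curr_aa not in AMINO_ACIDS:
        raise UnknownResidueTypeError(f"unknown amino acid {curr_aa!r}")
    if prev_aa is not None and prev_aa not in AMINO_ACIDS:
        raise UnknownResidueTypeError(f"unknown amino acid {prev_aa!r}")
    curr_types = scheme.types_for(curr_aa)
    prev_types = (
        scheme.types_for(prev_aa) if prev_aa is not None else (None,) * scheme.n_samples
    )
    is_pro = curr_aa == "P"
    return tuple(
        _pair_symbol(p, c, is_pro) for p, c in zip(prev_types, curr_types)
    )


@dataclass
class AssignmentTable:
    """Per-residue assignment status derived from a labeling scheme.

    ``table`` has one row per residue with columns ``residue_id`` (1-based),
    ``aa``, ``code`` (the per-sample symbol tuple), ``status`` in
    {"assigned", "ambiguous", "invisible"} and ``k`` (number of residues
    sharing the code; 1 for assigned, >= 2 for ambiguous, 0 for invisible).
    """

    table: pd.DataFrame
    coverage: float

    @property
    def assigned(self) -> pd.DataFrame:
        return self.table[self.table.status == "assigned"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["code"] = out["code"].map(lambda c: "".join(map(str, c)))
        out.to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        counts = self.table.status.value_counts().to_dict()
        return {
            "n_residues": int(len(self.table)),
            "n_assigned": int(counts.get("assigned", 0)),
            "n_ambiguous": int(counts.get("ambiguous", 0)),
            "n_invisible": int(counts.get("invisible", 0)),
            "coverage": self.coverage,
        }


def _residue_codes(scheme: LabelingScheme, sequence: str) -> list:
    codes = []
    for i, aa in enumerate(sequence):
        prev = sequence[i - 1] if i > 0 else None
        codes.append(encode_pair(scheme, prev, aa))
    return codes


def assignment_table(scheme: LabelingScheme, sequence: str) -> AssignmentTable:
    """Assignment status of every residue of ``sequence`` under ``scheme``.

    A residue is *assigned* when its cross peak is visible (non-zero code in
    at least one sample) and no other residue shows the identical per-sample
    code.  Residues sharing a code are mutually ambiguous; all-zero codes are
    invisible.  Coverage counts assigned residues relative to all non-proline
    residues.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must contain at least 2 residues")
    codes = _residue_codes(scheme, sequence)
    zero = (0,) * scheme.n_samples
    multiplicity: dict = {}
    for code in codes:
        multiplicity[code] = multiplicity.get(code, 0) + 1
    rows = []
    for i, (aa, code) in enumerate(zip(sequence, codes)):
        if code == zero:
            status, k = "invisible", 0
        elif multiplicity[code] == 1:
            status, k = "assigned", 1
        else:
            status, k = "ambiguous", multiplicity[code]
        rows.append(
            {"residue_id": i + 1, "aa": aa, "code": code, "status": status, "k": k}
        )
    table = pd.DataFrame(rows)
    n_nonpro = int((table.aa != "P").sum())
    n_assigned = int((table.status == "assigned").sum())
    coverage = n_assigned / n_nonpro if n_nonpro else 0.0
    return AssignmentTable(table=table, coverage=coverage)


def predict_spectra(scheme: LabelingScheme, sequence: str) -> dict:
    """Predicted peak lists per sample.

    Returns ``{sample_index: DataFrame}`` where each frame lists the visible
    residues with boolean columns ``trosy``, ``hnco``, ``hnca``.  Prolines
    (and any residue without 15N in that sample) are absent.  Consistent with
    :func:`encode_pair` by construction: the HNCO/HNCA flags decode the same
    symbols.
    """
    codes = _residue_codes(scheme, sequence)
    out = {}
    for s in range(scheme.n_samples):
        rows = []
        for i, (aa, code) in enumerate(zip(sequence, codes)):
            sym = code[s]
            if sym == 0:
                continue
            rows.append(
                {
                    "residue_id": i + 1,
                    "aa": aa,
                    "trosy": True,
                    "hnco": sym in (2, 4),
                    "hnca": sym in (3, 4),
                }
            )
        out[s] = pd.DataFrame(
            rows, columns=["residue_id", "aa", "trosy", "hnco", "hnca"]
        ).astype({"residue_id": int, "trosy": bool, "hnco": bool, "hnca": bool})
    return out


class NoInformativeSchemeError(RuntimeError):
    """No scheme under the given stock yields any assigned residue."""


def _best_exact(sequence: str, stock: LabelingStock, n_samples: int):
    """Exhaustive search over all per-type token vectors for ``n_samples``."""
    aas = sorted(set(sequence))
    choices = [
        [tuple(v) for v in itertools.product(sorted(stock.tokens_for(aa)), repeat=n_samples)]
        for aa in aas
    ]
    best = None
    for combo in itertools.product(*choices):
        scheme = LabelingScheme({aa: vec for aa, vec in zip(aas, combo)})
        cov = assignment_table(scheme, sequence).coverage
        key = (-cov, scheme.total_price(stock), scheme._lex_key())
        if best is None or key < best[0]:
            best = (key, scheme, cov)
    return best[1], best[2]


def _best_greedy(sequence: str, stock: LabelingStock, n_samples: int):
    """Greedy heuristic: add samples one at a time; within a sample choose
    per-type tokens (cheapest first on ties) that maximize coverage given the
    samples fixed so far."""
    aas = sorted(set(sequence))
    assign: dict = {aa: () for aa in aas}
    for _ in range(n_samples):
        for aa in assign:
            assign[aa] = assign[aa] + ("X",)
        for aa in aas:
            options = sorted(
                stock.tokens_for(aa),
                key=lambda t: (stock.price_of(aa, t), TOKEN_ORDER[t]),
            )
            scored = []
            for tok in options:
                trial = dict(assign)
                trial[aa] = assign[aa][:-1] + (tok,)
                cov = assignment_table(LabelingScheme(trial), sequence).coverage
                scored.append((-cov, stock.price_of(aa, tok), TOKEN_ORDER[tok], tok))
            assign[aa] = assign[aa][:-1] + (min(scored)[3],)
    scheme = LabelingScheme(assign)
    return scheme, assignment_table(scheme, sequence).coverage


def design_scheme(
    sequence: str,
    stock: LabelingStock | None = None,
    max_samples: int = 5,
    exact_space_limit: int = 300_000,
) -> LabelingScheme:
    """Design a labeling scheme for ``sequence``.

    Searches sample counts 1..``max_samples`` and returns the scheme with the
    smallest number of samples that achieves the maximal attainable coverage;
    ties are broken by lower total price, then by lexicographic order of the
    token matrix (deterministic).  The search is exact (full enumeration over
    per-type token vectors) while the scheme space is at most
    ``exact_space_limit``; beyond that a documented greedy heuristic is used.
    """
    if max_samples < 1:
        raise ValueError("max_samples must be >= 1")
    if stock is None:
        stock = LabelingStock.uniform(sorted(set(sequence)))
    aas = sorted(set(sequence))
    results = []
    for n in range(1, max_samples + 1):
        space = 1
        for aa in aas:
            space *= len(stock.tokens_for(aa)) ** n
            if space > exact_space_limit:
                break
        if space <= exact_space_limit:
            scheme, cov = _best_exact(sequence, stock, n)
        else:
            scheme, cov = _best_greedy(sequence, stock, n)
        results.append((cov, n, scheme))
        if cov >= _coverage_upper_bound(sequence, stock):
            break
    best_cov = max(cov for cov, _, _ in results)
    if best_cov == 0.0:
        raise NoInformativeSchemeError(
            "no scheme under this stock assigns any residue"
        )
    for cov, _, scheme in results:
        if cov == best_cov:
            return scheme
    raise AssertionError("unreachable")


def _coverage_upper_bound(sequence: str, stock: LabelingStock) -> float:
    """Coverage ceiling from type-pair multiplicity and 15N availability.

    The code of residue *i* is a function of the (previous, current)
    amino-acid *types* only, so residues sharing a type pair can never be
    told apart; residues whose type offers neither N nor D can never be
    visible.
    """
    pairs = []
    for i, aa in enumerate(sequence):
        prev = sequence[i - 1] if i > 0 else None
        pairs.append((prev, aa))
    counts: dict = {}
    for p in pairs:
        counts[p] = counts.get(p, 0) + 1
    n_nonpro = sum(1 for aa in sequence if aa != "P")
    n_ok = 0
    for (prev, aa), c in counts.items():
        if c > 1 or aa == "P":
            continue
        if stock.tokens_for(aa) & {"N", "D"}:
            n_ok += 1
    return n_ok / n_nonpro if n_nonpro else 0.0


def read_fasta_sequence(path) -> str:
    """Read a single-record FASTA file into a plain residue string."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    return str(records[0].seq).upper()
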