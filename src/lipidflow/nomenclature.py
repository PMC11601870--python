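"""Lipid shorthand nomenclature: parsing, class sets, and chain-based categories.

Lipid names follow the RefMet-style shorthand used in untargeted lipidomics:
a class token (``PC``, ``TAG``, ``Cer`` ...) followed by either a sum
composition (``PC 40:6`` — total carbons:double bonds, individual chains
unknown) or chain-resolved composition (``PC 18:0_22:6``), where ``/``
separates chains of known sn-position and ``_`` chains of unknown position.
Ether (alkyl/alkenyl) linkages carry an ``O-``/``P-`` prefix on the chain and
promote the species into the ether class (``PE O-18:1_22:5`` is an ``O-PE``).
Sphingolipid bases use the ``d``/``t`` hydroxylation prefix (``SM d18:1/24:1``,
or the base-containing sum form ``SM d42:2``); ceramides also appear in
N-acyl-only shorthand (``Cer C16:0``, base left implicit). Deuterated internal
standards carry a ``(d7)``-style suffix.

This module turns those strings into structured :class:`LipidAnnotation`
objects and builds the lipid sets (classes, TAG chain-length/saturation
categories, PUFA-containing selections) consumed by the enrichment and
composition stages.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "ChainSpec",
    "LipidAnnotation",
    "LipidParseError",
    "LipidSetCatalog",
    "TagCategory",
    "PufaSelection",
    "parse_lipid_name",
    "annotation_to_name",
    "build_class_sets",
    "assign_tag_category",
    "select_pufa_species",
    "read_annotation_table",
    "write_annotation_table",
    "CLASS_VOCABULARY",
    "DEFAULT_ANCHOR_CHAINS",
    "ARA_CHAIN",
    "DHA_CHAIN",
]


class LipidParseError(ValueError):
    """Raised when a lipid name cannot be parsed; carries the offending token."""

    def __init__(self, raw_name: str, token: str, reason: str = ""):
        self.raw_name = raw_name
        self.token = token
        msg = f"cannot parse lipid name {raw_name!r}: bad token {token!r}"
        if reason:
            msg += f" ({reason})"
        super().__init__(msg)


# Controlled class vocabulary (editable configuration data). Seeded with the
# classes named in figures plus RefMet main classes at comparable granularity;
# CE and SiE are kept distinct to separate cholesteryl from sitosteryl esters.
CLASS_VOCABULARY: tuple[str, ...] = (
    "PC", "PE", "PS", "PG", "PI", "PA",
    "O-PC", "O-PE", "O-PS", "O-PG", "O-PI",
    "LPC", "LPE", "LPS", "LPG", "LPI", "LPA",
    "O-LPC", "O-LPE",
    "MAG", "DAG", "TAG",
    "SM", "Cer", "CerP", "HexCer", "Hex2Cer", "SHexCer", "GM3", "SPB",
    "Car", "CE", "SiE", "Chol",
    "FFA", "FAHFA", "NAE", "oxylipin",
    "BMP", "CL", "DGTS", "PMeOH", "Sulfatide",
)

_CLASS_ALIASES: Mapping[str, str] = {
    "Chol Ester": "CE",
    "ChE": "CE",
    "CholE": "CE",
    "cholesterol": "Chol",
    "Cholesterol": "Chol",
    "AcCa": "Car",
    "CAR": "Car",
    "TG": "TAG",
    "DG": "DAG",
    "MG": "MAG",
}

# Number of acyl/alkyl chains a fully resolved species of each class carries.
_EXPECTED_CHAINS: Mapping[str, int] = {
    "PC": 2, "PE": 2, "PS": 2, "PG": 2, "PI": 2, "PA": 2,
    "O-PC": 2, "O-PE": 2, "O-PS": 2, "O-PG": 2, "O-PI": 2,
    "LPC": 1, "LPE": 1, "LPS": 1, "LPG": 1, "LPI": 1, "LPA": 1,
    "O-LPC": 1, "O-LPE": 1,
    "MAG": 1, "DAG": 2, "TAG": 3,
    "SM": 2, "Cer": 2, "CerP": 2, "HexCer": 2, "Hex2Cer": 2,
    "SHexCer": 2, "GM3": 2, "SPB": 1,
    "Car": 1, "CE": 1, "SiE": 1, "Chol": 0,
    "FFA": 1, "FAHFA": 2, "NAE": 1, "oxylipin": 1,
    "BMP": 2, "CL": 4, "DGTS": 2, "PMeOH": 2, "Sulfatide": 2,
}

# Multi-chain sphingolipid classes where a single d/t-prefixed token denotes a
# base-containing sum composition ("SM d42:2") rather than a lone base chain.
_SPHINGO_SUM_CLASSES = frozenset(
    {"SM", "Cer", "CerP", "HexCer", "Hex2Cer", "SHexCer", "GM3", "Sulfatide"}
)

_CHAIN_RE = re.compile(
    r"^(?P<ether>[OP]-)?(?P<acylC>C)?(?P<sph>[dt])?"
    r"(?P<c>\d+):(?P<db>\d+)"
    r"(?P<oh>\((?:\d*)OH\))?"
    r"(?P<iso>\(d\d+\))?$"
)
_CHAIN_START_RE = re.compile(r"^(?:[OP]-)?C?[dt]?\d+:\d+")
_ISO_SUFFIX_RE = re.compile(r"\((d\d+)\)\s*$")
# An en dash, or a hyphen sandwiched between a chain end and a chain start,
# separates chains in ISTD-style names ("PC 15:0-18:1(d7)"); a hyphen after
# O/P does not.
_DASH_SEP_RE = re.compile(r"(?<=[)\d])[-–](?=[OPdt]?-?\d+:)")


@dataclass(frozen=True)
class ChainSpec:
    """One fatty acyl / alkyl / sphingoid chain.

    ``ether_type`` is ``"O"`` (alkyl), ``"P"`` (alkenyl / plasmalogen) or
    ``None``; ``sphingoid`` marks a long-chain base, whose ``d``/``t`` prefix
    fixes ``hydroxyl_count`` at 2 or 3.
    """

    carbons: int
    double_bonds: int
    ether_type: Optional[str] = None
    hydroxyl_count: int = 0
    isotope_label: Optional[str] = None
    sphingoid: bool = False

    def __post_init__(self):
        if self.carbons < 0 or self.double_bonds < 0:
            raise ValueError("carbons and double_bonds must be nonnegative")
        if 0 < self.carbons < self.double_bonds:
            raise ValueError(
                f"chain {self.carbons}:{self.double_bonds} has more double "
                "bonds than carbons"
            )

    @property
    def ether_link(self) -> bool:
        return self.ether_type is not None

    def to_token(self, acyl_only: bool = False) -> str:
        parts = []
        if self.ether_type:
            parts.append(f"{self.ether_type}-")
        if acyl_only:
            parts.append("C")
        if self.sphingoid:
            parts.append("d" if self.hydroxyl_count <= 2 else "t")
        parts.append(f"{self.carbons}:{self.double_bonds}")
        if self.hydroxyl_count and not self.sphingoid:
            parts.append("(OH)" if self.hydroxyl_count == 1
                         else f"({self.hydroxyl_count}OH)")
        if self.isotope_label:
            parts.append(f"({self.isotope_label})")
        return "".join(parts)


@dataclass(frozen=True)
class LipidAnnotation:
    """Parsed identity of a lipid feature.

    ``lipid_class`` is ``None`` only for unannotated (MSI level 4) features.
    When ``chains`` is nonempty the totals equal the chain sums; ``acyl_only``
    marks ceramide N-acyl shorthand whose implicit d18:1 base is *not*
    included in the totals.
    """

    raw_name: str
    lipid_class: Optional[str]
    chains: tuple[ChainSpec, ...] = ()
    total_carbons: int = 0
    total_double_bonds: int = 0
    sum_level_only: bool = False
    sn_known: bool = False
    acyl_only: bool = False
    sphingoid_sum: bool = False
    msi_level: int = 2
    esi_mode: Optional[str] = None
    isotope_label: Optional[str] = None
    feature_id: Optional[str] = None

    def __post_init__(self):
        if self.msi_level not in (1, 2, 3, 4):
            raise ValueError("msi_level must be 1-4")
        if (self.msi_level == 4) != (self.lipid_class is None):
            raise ValueError("msi_level 4 if and only if lipid_class is absent")
        if self.chains:
            tc = sum(c.carbons for c in self.chains)
            td = sum(c.double_bonds for c in self.chains)
            if (tc, td) != (self.total_carbons, self.total_double_bonds):
                raise ValueError(
                    f"{self.raw_name!r}: totals {self.total_carbons}:"
                    f"{self.total_double_bonds} != chain sum {tc}:{td}"
                )

    @property
    def is_istd(self) -> bool:
        return self.isotope_label is not None

    @property
    def key(self) -> str:
        return self.feature_id if self.feature_id is not None else self.raw_name

    def structural_eq(self, other: "LipidAnnotation") -> bool:
        """Equality of parsed structure, ignoring provenance fields."""
        strip = dict(raw_name="", feature_id=None, esi_mode=None, msi_level=2)
        return replace(self, **strip) == replace(other, **strip)


def _parse_chain(token: str, raw_name: str) -> ChainSpec:
    m = _CHAIN_RE.match(token)
    if not m:
        raise LipidParseError(raw_name, token, "not a chain token")
    carbons = int(m.group("c"))
    db = int(m.group("db"))
    ether = m.group("ether")[0] if m.group("ether") else None
    sph = m.group("sph")
    oh = 0
    if m.group("oh"):
        digits = re.search(r"\d+", m.group("oh"))
        oh = int(digits.group()) if digits else 1
    if sph:
        oh = 2 if sph == "d" else 3
    iso = m.group("iso")[1:-1] if m.group("iso") else None
    try:
        return ChainSpec(carbons, db, ether_type=ether, hydroxyl_count=oh,
                         isotope_label=iso, sphingoid=sph is not None)
    except ValueError as exc:
        raise LipidParseError(raw_name, token, str(exc)) from exc


def _resolve_class(class_str: str, raw_name: str) -> str:
    token = _CLASS_ALIASES.get(class_str, class_str)
    if token not in CLASS_VOCABULARY:
        raise LipidParseError(raw_name, class_str, "unknown lipid class")
    return token


def parse_lipid_name(
    raw_name: str,
    msi_level: int = 2,
    esi_mode: Optional[str] = None,
    feature_id: Optional[str] = None,
) -> LipidAnnotation:
    """Parse a lipid shorthand name into a :class:`LipidAnnotation`.

    The parse is deterministic and never falls back to a guessed class: any
    unrecognized token raises :class:`LipidParseError`.

    Examples
    --------
    >>> parse_lipid_name("PC 18:0_22:6").total_carbons
    40
    >>> parse_lipid_name("PE O-18:1_22:5").lipid_class
    'O-PE'
    >>> parse_lipid_name("TAG 48:0").sum_level_only
    True
    """
    if not raw_name or not raw_name.strip():
        raise LipidParseError(raw_name, raw_name, "empty name")
    s = raw_name.strip()

    # pull a trailing "(d7)" isotope suffix off class-only / sum-level names
    tokens = s.split()
    if not tokens:
        raise LipidParseError(raw_name, raw_name, "empty name")

    chain_idx = None
    for i, tok in enumerate(tokens):
        if _CHAIN_START_RE.match(_DASH_SEP_RE.sub("_", tok)):
            chain_idx = i
            break

    if chain_idx is None or chain_idx == 0:
        if chain_idx == 0:
            raise LipidParseError(raw_name, tokens[0], "missing class token")
        # class-only name, e.g. "cholesterol (d7)"
        rest = s
        iso = None
        m = _ISO_SUFFIX_RE.search(rest)
        if m:
            iso = m.group(1)
            rest = rest[: m.start()].strip()
        cls = _resolve_class(rest, raw_name)
        if _EXPECTED_CHAINS.get(cls, 0) != 0:
            raise LipidParseError(raw_name, rest, "class requires chains")
        return LipidAnnotation(
            raw_name=raw_name, lipid_class=cls, msi_level=msi_level,
            esi_mode=esi_mode, isotope_label=iso, feature_id=feature_id,
        )

    class_str = " ".join(tokens[:chain_idx])
    chain_str = _DASH_SEP_RE.sub("_", " ".join(tokens[chain_idx:]))
    lipid_class = _resolve_class(class_str, raw_name)

    sn_known = "/" in chain_str
    if "/" in chain_str and "_" in chain_str:
        sn_known = False  # mixed separators: positions not fully known
    chain_tokens = re.split(r"[/_]", chain_str)
    acyl_only = any(t.startswith("C") and t[1:2].isdigit() for t in chain_tokens)
    if acyl_only and len(chain_tokens) != 1:
        raise LipidParseError(raw_name, chain_str,
                              "acyl-only shorthand takes a single chain")
    chains = tuple(_parse_chain(t, raw_name) for t in chain_tokens)

    if chains and chains[0].ether_link and not lipid_class.startswith("O-"):
        promoted = f"O-{lipid_class}"
        lipid_class = _resolve_class(promoted, raw_name)

    expected = _EXPECTED_CHAINS.get(lipid_class)
    sum_level = False
    sphingoid_sum = False
    if len(chains) == 1 and expected is not None and expected > 1:
        only = chains[0]
        if acyl_only:
            pass  # ceramide N-acyl shorthand: single chain, base implicit
        elif only.sphingoid and lipid_class in _SPHINGO_SUM_CLASSES:
            sum_level = True
            sphingoid_sum = True
        else:
            sum_level = True
    elif expected is not None and len(chains) not in (1, expected):
        raise LipidParseError(
            raw_name, chain_str,
            f"{lipid_class} expects {expected} chains, got {len(chains)}",
        )

    iso_labels = sorted({c.isotope_label for c in chains if c.isotope_label})
    isotope_label = iso_labels[0] if iso_labels else None

    total_c = sum(c.carbons for c in chains)
    total_db = sum(c.double_bonds for c in chains)
    if sum_level:
        chains = ()

    return LipidAnnotation(
        raw_name=raw_name,
        lipid_class=lipid_class,
        chains=chains,
        total_carbons=total_c,
        total_double_bonds=total_db,
        sum_level_only=sum_level,
        sn_known=sn_known and bool(chains),
        acyl_only=acyl_only,
        sphingoid_sum=sphingoid_sum,
        msi_level=msi_level,
        esi_mode=esi_mode,
        isotope_label=isotope_label,
        feature_id=feature_id,
    )


def annotation_to_name(ann: LipidAnnotation) -> str:
    """Write an annotation back to canonical shorthand (round-trip safe)."""
    if ann.lipid_class is None:
        raise ValueError("cannot name an unannotated (MSI 4) feature")
    cls = ann.lipid_class
    if ann.chains and ann.chains[0].ether_link and cls.startswith("O-"):
        cls = cls[2:]  # the chain prefix carries the ether mark
    if not ann.chains and not ann.sum_level_only:
        name = cls if cls != "Chol" else "cholesterol"
        if ann.isotope_label:
            name += f" ({ann.isotope_label})"
        return name
    if ann.sum_level_only:
        prefix = "d" if ann.sphingoid_sum else ""
        name = f"{cls} {prefix}{ann.total_carbons}:{ann.total_double_bonds}"
        if ann.isotope_label:
            name += f"({ann.isotope_label})"
        return name
    sep = "/" if ann.sn_known else "_"
    body = sep.join(
        c.to_token(acyl_only=ann.acyl_only and i == 0)
        for i, c in enumerate(ann.chains)
    )
    return f"{cls} {body}"


@dataclass
class LipidSetCatalog:
    """Named lipid sets (feature-id lists) for enrichment and composition."""

    sets: dict[str, list[str]]
    set_kind: str = "class"

    def __post_init__(self):
        allowed = {"class", "chain_category", "pufa_selection", "custom"}
        if self.set_kind not in allowed:
            raise ValueError(f"set_kind must be one of {sorted(allowed)}")

    def filter_universe(self, universe: Iterable[str]) -> "LipidSetCatalog":
        uni = set(universe)
        return LipidSetCatalog(
            sets={k: [i for i in v if i in uni] for k, v in self.sets.items()},
            set_kind=self.set_kind,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.sets, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path, set_kind: str = "custom") -> "LipidSetCatalog":
        with open(path) as fh:
            return cls(sets=json.load(fh), set_kind=set_kind)


def build_class_sets(
    annotations: Sequence[LipidAnnotation], min_size: int = 10
) -> LipidSetCatalog:
    """One lipid set per class with at least ``min_size`` members.

    MSI level 4 (unannotated) features and internal standards are excluded.
    Class sets are disjoint by construction: each feature has one class.
    """
    if not annotations:
        raise ValueError("empty annotation list")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    by_class: dict[str, list[str]] = {}
    for ann in annotations:
        if ann.msi_level == 4 or ann.is_istd or ann.lipid_class is None:
            continue
        by_class.setdefault(ann.lipid_class, []).append(ann.key)
    sets = {k: sorted(v) for k, v in by_class.items() if len(v) >= min_size}
    return LipidSetCatalog(sets=sets, set_kind="class")


@dataclass(frozen=True)
class TagCategory:
    saturation: str        # saturated | monounsaturated | polyunsaturated
    chain_length: str      # short-chain | medium-chain | long-chain | very-long-chain | other
    flagged: bool = False  # carbons outside the 30-60 binning range


# Closed total-carbon bins for TAG chain-length categories.
_TAG_BINS = (
    (30, 48, "short-chain"),
    (49, 52, "medium-chain"),
    (53, 55, "long-chain"),
    (56, 60, "very-long-chain"),
)


def assign_tag_category(annotation: LipidAnnotation) -> TagCategory:
    """Saturation and chain-length category for a TAG species.

    Saturation: 0 double bonds saturated, 1 monounsaturated, >=2
    polyunsaturated. Chain length by total carbons: short C30-48, medium
    C49-52, long C53-55, very-long C56-60; outside 30-60 -> "other", flagged.
    """
    if annotation.lipid_class != "TAG":
        raise ValueError(f"{annotation.raw_name!r} is not a TAG species")
    db = annotation.total_double_bonds
    sat = ("saturated" if db == 0
           else "monounsaturated" if db == 1
           else "polyunsaturated")
    tc = annotation.total_carbons
    for lo, hi, label in _TAG_BINS:
        if lo <= tc <= hi:
            return TagCategory(sat, label, flagged=False)
    return TagCategory(sat, "other", flagged=True)


DEFAULT_ANCHOR_CHAINS: tuple[tuple[int, int], ...] = (
    (16, 0), (16, 1), (18, 0), (18, 1),
)
ARA_CHAIN: tuple[int, int] = (20, 4)
DHA_CHAIN: tuple[int, int] = (22, 6)


@dataclass
class PufaSelection:
    selected: list[str]
    skipped_sum_level: list[str]


def select_pufa_species(
    annotations: Sequence[LipidAnnotation],
    classes: Sequence[str],
    target_chains: Sequence[tuple[int, int]] = (ARA_CHAIN, DHA_CHAIN),
    anchor_chains: Sequence[tuple[int, int]] = DEFAULT_ANCHOR_CHAINS,
) -> PufaSelection:
    """Select chain-resolved species carrying one anchor plus one target chain.

    A species qualifies when its chain multiset contains at least one anchor
    (by default 16:0, 16:1, 18:0 or 18:1) and, on a *different* chain, one of
    the target PUFA compositions (20:4 arachidonic or 22:6 docosahexaenoic),
    restricted to the named classes. Sum-composition-only species cannot be
    evaluated and are reported in ``skipped_sum_level``.
    """
    cls = set(classes)
    anchors = set(map(tuple, anchor_chains))
    targets = set(map(tuple, target_chains))
    selected: list[str] = []
    skipped: list[str] = []
    for ann in annotations:
        if ann.lipid_class not in cls or ann.is_istd:
            continue
        if ann.sum_level_only or not ann.chains:
            skipped.append(ann.key)
            continue
        comp = [(c.carbons, c.double_bonds) for c in ann.chains]
        hit = False
        for i, a in enumerate(comp):
            if a not in anchors:
                continue
            if any(j != i and b in targets for j, b in enumerate(comp)):
                hit = True
                break
        if hit:
            selected.append(ann.key)
    return PufaSelection(selected=selected, skipped_sum_level=skipped)


def read_annotation_table(path) -> list[LipidAnnotation]:
    """Read a TSV with columns feature_id, name, msi_level, esi_mode."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    out = []
    for row in df.itertuples(index=False):
        if int(row.msi_level) == 4:
            out.append(LipidAnnotation(
                raw_name=str(row.name), lipid_class=None, msi_level=4,
                esi_mode=row.esi_mode, feature_id=row.feature_id))
        else:
            out.append(parse_lipid_name(
                str(row.name), msi_level=int(row.msi_level),
                esi_mode=row.esi_mode, feature_id=row.feature_id))
    return out


def write_annotation_table(annotations: Sequence[LipidAnnotation], path) -> None:
    pd.DataFrame({
        "feature_id": [a.key for a in annotations],
        "name": [a.raw_name for a in annotations],
        "msi_level": [a.msi_level for a in annotations],
        "esi_mode": [a.esi_mode for a in annotations],
    }).to_csv(path, sep="\t", index=False)
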