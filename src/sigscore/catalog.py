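"""SIG reference catalogs: taxon identifiers, catalog I/O and validation.

A catalog holds the two antagonistic species interaction groups used for
dysbiosis scoring — SIG1 (37 species associated with worse outcome, split
into an oral-cavity cluster and a gut-resident obligate-anaerobe cluster)
and SIG2 (45 gut-resident butyrate producers associated with better
outcome) — together with the score thresholds, the *Akkermansia
muciniphila* identifier used to resolve gray-zone samples, and its
overabundance cutoff.

Only part of the published species lists is public; the shipped default
catalog contains every explicitly named member plus clearly flagged
placeholder entries padding each group to its exact published size, so the
real lists can be dropped in as a JSON file without code changes.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import CatalogError, ValidationError

_SGB_RE = re.compile(r"SGB\d+", re.IGNORECASE)
_RANK_PREFIX_RE = re.compile(r"^[a-z]__", re.IGNORECASE)
_WS_RE = re.compile(r"\s+")

LABEL_SIG1 = "SIG1+"
LABEL_SIG2 = "SIG2+"
LABEL_GRAY = "GRAY"


@dataclass(frozen=True)
class TaxonId:
    """A normalized taxon identity.

    ``canonical`` is the lower-cased species token with underscore/whitespace
    variants collapsed; ``sgb`` carries a MetaPhlAn species-level genome bin
    code (e.g. ``"SGB9226"``) when one was present in the raw name.
    """

    raw_name: str
    canonical: str
    sgb: str | None = None
    placeholder: bool = False

    def __post_init__(self) -> None:
        if not self.canonical:
            raise ValidationError("TaxonId.canonical must be non-empty")
        if self.sgb is not None and not re.fullmatch(r"SGB\d+", self.sgb):
            raise ValidationError(f"malformed SGB code: {self.sgb!r}")


def normalize_taxon_name(raw: str, *, sgb: str | None = None,
                         placeholder: bool = False) -> TaxonId:
    """Normalize a raw taxon name into a :class:`TaxonId`.

    Accepts full MetaPhlAn clade strings (``k__Bacteria|...|s__Genus_species``
    or ``...|t__SGB9226``), plain species names, and names with a trailing SGB
    code. Spelling variants differing only in case, separators, or the clade
    prefix map to one canonical form; an embedded SGB code is extracted.
    """
    if raw is None or not str(raw).strip():
        raise ValidationError("taxon name must be a non-empty string")
    raw = str(raw).strip()

    found = _SGB_RE.search(raw)
    found_sgb = "SGB" + found.group(0)[3:] if found else None
    sgb = sgb if sgb is not None else found_sgb

    # Walk clade segments from the most specific; the canonical name is the
    # last segment that is not purely an SGB token.
    canonical = ""
    for segment in reversed(raw.split("|")):
        token = _RANK_PREFIX_RE.sub("", segment.strip())
        token = _SGB_RE.sub(" ", token)
        token = _WS_RE.sub(" ", token.replace("_", " ")).strip().lower()
        if token:
            canonical = token
            break
    if not canonical:
        if sgb is None:
            raise ValidationError(f"cannot derive a canonical name from {raw!r}")
        canonical = sgb.lower()
    return TaxonId(raw_name=raw, canonical=canonical, sgb=sgb,
                   placeholder=placeholder)


@dataclass(frozen=True)
class SigCatalog:
    """The SIG1/SIG2 reference sets plus classification constants.

    ``t_low`` and ``t_high`` bracket the score gray zone; ``akk_over_cutoff``
    is the *A. muciniphila* relative abundance (percent) above which a
    gray-zone sample is considered overabundant, hence dysbiotic.
    """

    sig1: tuple[TaxonId, ...]
    sig2: tuple[TaxonId, ...]
    sig1_oral: tuple[TaxonId, ...]
    akkermansia: TaxonId
    t_low: float = 0.535
    t_high: float = 0.791
    akk_over_cutoff: float = 4.799

    @property
    def sig1_gut(self) -> tuple[TaxonId, ...]:
        oral = {t.canonical for t in self.sig1_oral}
        return tuple(t for t in self.sig1 if t.canonical not in oral)

    @property
    def n_sig1(self) -> int:
        return len(self.sig1)

    @property
    def n_sig2(self) -> int:
        return len(self.sig2)

    def validate(self, *, enforce_sizes: bool = True) -> "SigCatalog":
        """Check structural invariants, raising :class:`CatalogError` naming
        the first violated one. Returns self for chaining."""
        for name, group in (("sig1", self.sig1), ("sig2", self.sig2)):
            canon = [t.canonical for t in group]
            if len(set(canon)) != len(canon):
                dupes = sorted({c for c in canon if canon.count(c) > 1})
                raise CatalogError(f"duplicate canonical taxa in {name}: {dupes}")
        s1 = {t.canonical for t in self.sig1}
        s2 = {t.canonical for t in self.sig2}
        if s1 & s2:
            raise CatalogError(f"sig1 and sig2 overlap: {sorted(s1 & s2)}")
        oral = {t.canonical for t in self.sig1_oral}
        if not oral <= s1:
            raise CatalogError(
                f"sig1_oral entries outside sig1: {sorted(oral - s1)}")
        if enforce_sizes and (len(s1) != 37 or len(s2) != 45):
            raise CatalogError(
                f"default catalog must have |sig1| = 37 and |sig2| = 45, "
                f"got {len(s1)} and {len(s2)}")
        if self.akkermansia.canonical in s1 | s2:
            raise CatalogError("akkermansia must not be a member of sig1 or sig2")
        if not (0.0 < self.t_low < self.t_high < 1.0):
            raise CatalogError(
                f"thresholds must satisfy 0 < t_low < t_high < 1, "
                f"got {self.t_low} and {self.t_high}")
        if self.akk_over_cutoff <= 0:
            raise CatalogError("akk_over_cutoff must be positive")
        return self

    def content_hash(self) -> str:
        """SHA-256 over the canonical JSON serialization (provenance)."""
        payload = json.dumps(_catalog_to_dict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def _entry_to_taxon(entry: dict | str) -> TaxonId:
    if isinstance(entry, str):
        return normalize_taxon_name(entry)
    return normalize_taxon_name(entry["name"], sgb=entry.get("sgb"),
                                placeholder=bool(entry.get("placeholder", False)))


def _taxon_to_entry(t: TaxonId) -> dict:
    entry: dict = {"name": t.raw_name}
    if t.sgb is not None:
        entry["sgb"] = t.sgb
    if t.placeholder:
        entry["placeholder"] = True
    return entry


def _catalog_to_dict(cat: SigCatalog) -> dict:
    return {
        "sig1": [_taxon_to_entry(t) for t in cat.sig1],
        "sig2": [_taxon_to_entry(t) for t in cat.sig2],
        "sig1_oral": [t.raw_name for t in cat.sig1_oral],
        "akkermansia": _taxon_to_entry(cat.akkermansia),
        "thresholds": {
            "t_low": cat.t_low,
            "t_high": cat.t_high,
            "akk_over_cutoff": cat.akk_over_cutoff,
        },
    }


def catalog_from_dict(doc: dict, *, enforce_sizes: bool = True) -> SigCatalog:
    try:
        sig1 = tuple(_entry_to_taxon(e) for e in doc["sig1"])
        sig2 = tuple(_entry_to_taxon(e) for e in doc["sig2"])
        oral_names = {normalize_taxon_name(n).canonical for n in doc["sig1_oral"]}
        sig1_oral = tuple(t for t in sig1 if t.canonical in oral_names)
        missing = oral_names - {t.canonical for t in sig1_oral}
        if missing:
            raise CatalogError(f"sig1_oral names not found in sig1: {sorted(missing)}")
        akk = _entry_to_taxon(doc["akkermansia"])
        thr = doc.get("thresholds", {})
        cat = SigCatalog(
            sig1=sig1, sig2=sig2, sig1_oral=sig1_oral, akkermansia=akk,
            t_low=float(thr.get("t_low", 0.535)),
            t_high=float(thr.get("t_high", 0.791)),
            akk_over_cutoff=float(thr.get("akk_over_cutoff", 4.799)),
        )
    except KeyError as exc:
        raise CatalogError(f"catalog file missing key: {exc}") from exc
    return cat.validate(enforce_sizes=enforce_sizes)


def load_catalog(path: str | Path, *, enforce_sizes: bool = True) -> SigCatalog:
    """Load and validate a SIG catalog from its JSON file format."""
    with open(path) as fh:
        doc = json.load(fh)
    return catalog_from_dict(doc, enforce_sizes=enforce_sizes)


def write_catalog(catalog: SigCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_catalog_to_dict(catalog), fh, indent=1)
        fh.write("\n")


_DEFAULT: SigCatalog | None = None


def default_catalog() -> SigCatalog:
    """The shipped 37/45 catalog (named species + flagged placeholders)."""
    global _DEFAULT
    if _DEFAULT is None:
        with resources.files("sigscore.data").joinpath(
                "default_catalog.json").open() as fh:
            _DEFAULT = catalog_from_dict(json.load(fh))
    return _DEFAULT
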