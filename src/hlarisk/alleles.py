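"""HLA allele names at two-field (four-digit) resolution.

Classical class I and II loci are highly polymorphic; this package analyses
carriage of individual two-field alleles (e.g. ``HLA-DRB1*04:06``, the
allele-group field followed by the protein field) at the four loci typed in
the cohort: HLA-A, HLA-B, HLA-C and HLA-DRB1.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass


class Locus(enum.Enum):
    """Classical HLA loci considered in the analysis."""

    A = "A"
    B = "B"
    C = "C"
    DRB1 = "DRB1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class AlleleParseError(ValueError):
    """Raised when a string cannot be interpreted as a two-field HLA allele."""


@dataclass(frozen=True, order=True)
class HlaAllele:
    """A two-field HLA allele: locus, allele-group field and protein field.

    The canonical rendering is ``HLA-<locus>*<field1>:<field2>``, e.g.
    ``HLA-A*24:02``. Parsing a canonical string and re-rendering it is the
    identity.
    """

    locus: Locus
    field1: str
    field2: str

    def __post_init__(self) -> None:
        for field in (self.field1, self.field2):
            if not re.fullmatch(r"\d{2,3}", field):
                raise AlleleParseError(
                    f"allele field {field!r} is not a 2-3 digit group"
                )

    @property
    def name(self) -> str:
        """Canonical name, ``HLA-<locus>*<f1>:<f2>``."""
        return f"HLA-{self.locus.value}*{self.field1}:{self.field2}"

    @property
    def short_name(self) -> str:
        """Name without the ``HLA-`` prefix, as usually printed in tables."""
        return f"{self.locus.value}*{self.field1}:{self.field2}"

    def __str__(self) -> str:
        return self.name


_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(?P<locus>A|B|C|DRB1)\*(?P<fields>[\d:]+[A-Z]?)$"
)


def parse_allele(text: str, locus: Locus | None = None) -> HlaAllele:
    """Parse an HLA allele name into its locus and two fields.

    Accepts the canonical ``HLA-A*24:02``, the prefix-free ``A*24:02``, and a
    bare field pair ``24:02`` when ``locus`` is given explicitly. Resolution
    beyond two fields (e.g. a synonymous or intronic suffix) is truncated
    with a warning; expression suffix letters are dropped likewise.

    Raises
    ------
    AlleleParseError
        If the string is empty, the locus is unknown, the separator structure
        is wrong (e.g. ``HLA-B*1502`` without a colon), or a field is not a
        2-3 digit group.
    """
    if not text or not text.strip():
        raise AlleleParseError("empty allele name")
    token = text.strip()

    m = _ALLELE_RE.match(token)
    if m:
        locus = Locus(m.group("locus"))
        fields_part = m.group("fields")
    else:
        if "*" in token or token.startswith("HLA"):
            raise AlleleParseError(f"malformed HLA allele name: {token!r}")
        if locus is None:
            raise AlleleParseError(
                f"bare allele fields {token!r} require an explicit locus"
            )
        fields_part = token

    if fields_part and fields_part[-1].isalpha():
        warnings.warn(
            f"dropping expression suffix {fields_part[-1]!r} from {token!r}",
            stacklevel=2,
        )
        fields_part = fields_part[:-1]
    fields = fields_part.split(":")
    if len(fields) < 2:
        raise AlleleParseError(
            f"allele {token!r} lacks two colon-separated fields"
        )
    if len(fields) > 2:
        warnings.warn(
            f"truncating {token!r} to two-field resolution", stacklevel=2
        )
        fields = fields[:2]
    f1, f2 = fields
    if not re.fullmatch(r"\d{2,3}", f1) or not re.fullmatch(r"\d{2,3}", f2):
        raise AlleleParseError(f"non-numeric allele fields in {token!r}")
    return HlaAllele(locus=locus, field1=f1, field2=f2)
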