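"""The metabolite panel: the ordered set of perfusate analytes under monitoring.

The default panel is the 25-analyte perfusate assay used for hourly sampling
during normothermic liver perfusion: 18 common amino acids, ammonia, urea,
glucose, lactate, acetoacetate (ACAC) and albumin.  Panel order matters: it
fixes the column layout of unfolded data matrices and the numbering used in
contribution and VIP reports (1-based, as in assay tables).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ValidationError

#: Canonical 25-metabolite perfusate panel, in assay-table order (1-based
#: numbering: #1 ACAC ... #25 Valine).
DEFAULT_METABOLITES: tuple[str, ...] = (
    "ACAC",
    "Alanine",
    "Albumin",
    "Ammonia",
    "Arginine",
    "Asparagine",
    "Aspartate",
    "Glucose",
    "Glutamate",
    "Glutamine",
    "Glycine",
    "Histidine",
    "Isoleucine",
    "Lactate",
    "Leucine",
    "Lysine",
    "Methionine",
    "Ornithine",
    "Phenylalanine",
    "Proline",
    "Serine",
    "Threonine",
    "Tyrosine",
    "Urea",
    "Valine",
)


@dataclass(frozen=True)
class MetabolitePanel:
    """Ordered, unique list of metabolite names.

    Numbering is 1-based (``name_of(18) == "Ornithine"`` for the default
    panel) to match how analytes are referred to in assay tables; array
    indexing elsewhere in the package is 0-based via :meth:`index_of`.
    """

    names: tuple[str, ...] = field(default=DEFAULT_METABOLITES)

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValidationError("panel metabolite names must be unique")
        if not self.names:
            raise ValidationError("panel must contain at least one metabolite")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def name_of(self, number: int) -> str:
        """Name of the metabolite with 1-based panel number ``number``."""
        if not 1 <= number <= len(self.names):
            raise IndexError(f"metabolite number {number} outside 1..{len(self.names)}")
        return self.names[number - 1]

    def number_of(self, name: str) -> int:
        """1-based panel number of ``name``."""
        return self.index_of(name) + 1

    def index_of(self, name: str) -> int:
        """0-based array index of ``name``."""
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"metabolite {name!r} not in panel") from None


def default_panel() -> MetabolitePanel:
    """The standard 25-metabolite perfusate panel in assay-table order."""
    return MetabolitePanel(DEFAULT_METABOLITES)
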