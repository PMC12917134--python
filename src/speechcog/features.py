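"""Named feature vectors with per-feature validity flags.

Every extractor in this package reports features through :class:`FeatureVector`
so that degenerate inputs (no nouns, no pauses, a single sentence, ...) yield
an explicit invalid flag instead of a silent NaN or 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class FeatureVector:
    """Ordered mapping feature-name -> value, with validity flags.

    Invalid features carry ``nan`` as their value and ``False`` in ``valid``.
    """

    values: dict[str, float] = field(default_factory=dict)
    valid: dict[str, bool] = field(default_factory=dict)

    def set(self, name: str, value: float, valid: bool = True) -> None:
        self.values[name] = float(value) if valid else math.nan
        self.valid[name] = bool(valid)

    def set_invalid(self, name: str) -> None:
        self.set(name, math.nan, valid=False)

    def update(self, other: "FeatureVector") -> None:
        self.values.update(other.values)
        self.valid.update(other.valid)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def is_valid(self, name: str) -> bool:
        return self.valid[name]

    @property
    def names(self) -> list[str]:
        return list(self.values)

    def reorder(self, names: list[str]) -> "FeatureVector":
        """Return a copy restricted to ``names`` in that order."""
        out = FeatureVector()
        for n in names:
            if n not in self.values:
                raise KeyError(f"feature {n!r} was not computed")
            out.values[n] = self.values[n]
            out.valid[n] = self.valid[n]
        return out

    def to_dict(self) -> dict[str, float]:
        return dict(self.values)
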