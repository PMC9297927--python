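"""Cross types and inbreeding pedigree schemes.

An inbreeding scheme is an ordered list of crosses, always starting with an
outcross between an unrelated pair. The two built-in presets mirror the two
experimental regimes used for *Leptopilina*: *L. heterotoma* lines started
with a mother-son (M-S) cross followed by six brother-sister (B-S) crosses,
while *L. clavipes* lines went straight into six B-S crosses because females
of that species are reluctant to mate after cold storage.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class CrossStep(str, Enum):
    """One cross in a pedigree."""

    OUTCROSS = "outcross"
    MOTHER_SON = "mother_son"
    BROTHER_SISTER = "brother_sister"


@dataclass(frozen=True)
class CrossScheme:
    """An ordered pedigree of crosses, beginning with an outcross.

    Parameters
    ----------
    label : str
        Free-text name of the scheme.
    steps : tuple of CrossStep
        The cross carried out at each generation. ``steps[0]`` must be
        :attr:`CrossStep.OUTCROSS`; the brood of step ``i`` supplies the
        parents of step ``i + 1``.
    """

    label: str
    steps: tuple[CrossStep, ...]

    def __post_init__(self) -> None:
        steps = tuple(CrossStep(s) for s in self.steps)
        if not steps:
            raise ValueError("a cross scheme needs at least one step")
        if steps[0] is not CrossStep.OUTCROSS:
            raise ValueError("the first step of a scheme must be an outcross")
        object.__setattr__(self, "steps", steps)

    @classmethod
    def preset(cls, name: str, n_brother_sister: int = 6) -> "CrossScheme":
        """Return a built-in scheme.

        ``"heterotoma"``: outcross, M-S, then ``n_brother_sister`` B-S crosses.
        ``"clavipes"``: outcross, then ``n_brother_sister`` B-S crosses.
        """
        if name == "heterotoma":
            steps = (CrossStep.OUTCROSS, CrossStep.MOTHER_SON) + (
                CrossStep.BROTHER_SISTER,
            ) * n_brother_sister
        elif name == "clavipes":
            steps = (CrossStep.OUTCROSS,) + (
                CrossStep.BROTHER_SISTER,
            ) * n_brother_sister
        else:
            raise ValueError(f"unknown scheme preset {name!r}")
        return cls(label=name, steps=steps)

    def truncated(self, n_steps: int) -> "CrossScheme":
        """First ``n_steps`` crosses of this scheme."""
        return CrossScheme(label=f"{self.label}[:{n_steps}]", steps=self.steps[:n_steps])

    def generation_labels(self) -> list[str]:
        """Human-readable label for the brood produced by each step."""
        labels: list[str] = []
        n_bs = 0
        n_oc = 0
        for i, step in enumerate(self.steps):
            if step is CrossStep.OUTCROSS:
                n_oc += 1
                labels.append("outcross" if i == 0 else f"outcross {n_oc}")
            elif step is CrossStep.MOTHER_SON:
                labels.append("M-S")
            else:
                n_bs += 1
                labels.append(f"B-S {n_bs}")
        return labels
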