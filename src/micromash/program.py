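"""Mash program definition: ordered temperature rests with optional extensions.

A mash program is a sequence of constant-temperature stages (rests) followed by
a boil. Samples are drawn at the start and end of each stage and, where a stage
carries a time extension, at the end of that extension — an extra incubation at
the *same* temperature used to separate time-dependent from temperature-
dependent abundance changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["MashStage", "MashProgram", "SamplePoint", "default_program"]

#: valid sample-point labels, in within-stage order
POINT_LABELS = ("start", "end", "extension")


@dataclass(frozen=True)
class MashStage:
    """One constant-temperature rest (or the boil).

    Parameters
    ----------
    name:
        Stage label, e.g. ``"63C"`` or ``"boil"``.
    temperature:
        Stage temperature in °C; must lie in (0, 110].
    duration:
        Scheduled length of the stage in minutes (> 0).
    extension:
        Optional extra incubation at the stage temperature, in minutes
        (>= 0; 0 means the stage has no extension sample).
    is_boil:
        Marks the terminal boil stage.
    """

    name: str
    temperature: float
    duration: float
    extension: float = 0.0
    is_boil: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.temperature <= 110.0):
            raise ValueError(
                f"stage {self.name!r}: temperature {self.temperature} °C "
                "outside (0, 110]"
            )
        if self.duration <= 0:
            raise ValueError(f"stage {self.name!r}: duration must be > 0 min")
        if self.extension < 0:
            raise ValueError(f"stage {self.name!r}: extension must be >= 0 min")


@dataclass(frozen=True)
class SamplePoint:
    """A sampling instant: (stage, point label, minutes from stage start)."""

    stage: str
    point: str
    offset: float  # minutes from the start of the stage

    def __post_init__(self) -> None:
        if self.point not in POINT_LABELS:
            raise ValueError(f"unknown point label {self.point!r}")


@dataclass(frozen=True)
class MashProgram:
    """An ordered list of mash stages plus the sampling grid.

    If ``sample_points`` is omitted the conventional grid is used: start and
    end of every stage, plus the extension point for stages with a non-zero
    extension.
    """

    stages: tuple[MashStage, ...]
    sample_points: tuple[SamplePoint, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise ValueError("a mash program needs at least 2 stages")
        names = [s.name for s in self.stages]
        if len(set(names)) != len(names):
            raise ValueError("stage names must be unique")
        if not self.sample_points:
            object.__setattr__(
                self, "sample_points", tuple(self._default_grid())
            )
        by_name = {s.name: s for s in self.stages}
        for sp in self.sample_points:
            stage = by_name.get(sp.stage)
            if stage is None:
                raise ValueError(f"sample point refers to unknown stage {sp.stage!r}")
            if not (0.0 <= sp.offset <= stage.duration + stage.extension):
                raise ValueError(
                    f"sample point {sp.stage}/{sp.point} at {sp.offset} min lies "
                    f"outside the stage (duration {stage.duration} + extension "
                    f"{stage.extension} min)"
                )

    def _default_grid(self):
        for s in self.stages:
            yield SamplePoint(s.name, "start", 0.0)
            yield SamplePoint(s.name, "end", s.duration)
            if s.extension > 0:
                yield SamplePoint(s.name, "extension", s.duration + s.extension)

    @property
    def stage_names(self) -> list[str]:
        return [s.name for s in self.stages]

    def stage(self, name: str) -> MashStage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def next_stage(self, name: str) -> MashStage | None:
        names = self.stage_names
        i = names.index(name)
        return self.stages[i + 1] if i + 1 < len(self.stages) else None

    def grid(self) -> list[tuple[str, str]]:
        """The (stage, point) labels of the sampling grid, in program order."""
        return [(sp.stage, sp.point) for sp in self.sample_points]


def default_program(extension: float = 20.0) -> MashProgram:
    """The default multi-step program: rests at 52, 63, 73 and 78 °C and a
    boil, sampled after 30 min.

    The 63 °C rest runs 35 min and the boil sample is taken at 30 min; the
    remaining rest durations (30, 20, 15 min) and the per-rest ``extension``
    length (default 20 min) are package defaults and freely configurable.
    """
    return MashProgram(
        stages=(
            MashStage("52C", 52.0, 30.0, extension),
            MashStage("63C", 63.0, 35.0, extension),
            MashStage("73C", 73.0, 20.0, extension),
            MashStage("78C", 78.0, 15.0, extension),
            MashStage("boil", 102.0, 30.0, 0.0, is_boil=True),
        )
    )
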