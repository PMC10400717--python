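"""Error taxonomy of the simulator.

Growth code is written in a try/except style: a model proposes a new front
position, the engine vetoes it by raising one of the errors below, and the
model reacts (usually by trying another random position).  Every error leaves
the simulation state unchanged.
"""


class SimulationError(Exception):
    """Base class for all simulator-raised errors."""


class CollisionError(SimulationError):
    """The proposed structure overlaps an existing front.

    Carries the first colliding front found (`collider`, a FrontID).  A
    complete search can instead return all colliding fronts (`colliders`).
    """

    def __init__(self, collider, colliders=None):
        self.collider = collider
        self.colliders = colliders if colliders is not None else [collider]
        super().__init__(f"collision with front {collider}")


class InsideParentError(SimulationError):
    """new_pos lies inside the parent front's volume."""


class VolumeError(SimulationError):
    """A coordinate falls outside the simulation volume."""


class GridCompetitionError(SimulationError):
    """A grid lock could not be obtained within the timeout.

    Raised when several cores try to grow in the same region.  Callers retry
    immediately a few times or postpone the action to the next cycle.
    """

    def __init__(self, gid=None):
        self.gid = gid
        super().__init__(f"could not lock grid point {gid}")


class OverflowError(SimulationError):  # noqa: A001 - deliberate domain name
    """A fixed-size shared array (or a private section of one) is full.

    `array_name` tells the user which capacity parameter to increase.
    """

    def __init__(self, array_name):
        self.array_name = array_name
        super().__init__(f"array '{array_name}' is full; increase its capacity")


class NotSelfError(SimulationError):
    """A front method was called on a front other than the one currently
    dispatched for processing."""


class UsageError(SimulationError):
    """An API contract violation (e.g. retracting a non-terminal front)."""


class SamplingError(SimulationError):
    """Direction sampling could not satisfy its constraints after bounded
    retries."""
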