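import numpy as np

from patchkin.idealize import EventList


def events_from(levels, durations) -> EventList:
    """Build a contiguous EventList from parallel level/duration lists."""
    durations = np.asarray(durations, float)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return EventList(
        levels=np.asarray(levels, int),
        starts=starts,
        durations=durations,
        sweep_duration=float(durations.sum()),
    )
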