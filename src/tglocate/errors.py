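"""Exception hierarchy used across the pipeline."""


class TgLocateError(Exception):
    """Base class for all package errors."""


class ParameterError(TgLocateError, ValueError):
    """A caller-supplied parameter is out of range or inconsistent."""


class FormatError(TgLocateError, ValueError):
    """An input file violates its format contract (e.g. unsorted SAM,
    desynchronized FASTQ mates)."""


class ConsistencyError(TgLocateError, ValueError):
    """Two inputs that must agree do not (e.g. an orphan name missing from
    the transgene-side table, a coordinate beyond the chromosome end)."""


class StateError(TgLocateError, RuntimeError):
    """An operation was invoked before its prerequisite step (e.g. filtering
    before DTN computation)."""
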