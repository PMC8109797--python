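"""Self-tracing wrappers: call a function, get a provenance chunk for free.

:func:`make_traced` turns any callable into a :class:`TracedCallable`
bound to a report. Each invocation first serializes the call —
keyword-style, with literal arguments rendered as dialect literals and
data-bearing arguments referenced through placeholders — appends exactly
one complete chunk (optionally headed by a title and comment) to the
report, and only then performs the real call, returning its value
unmodified. This is the pattern a GUI or pipeline back-end uses to gain
a reproducibility layer without writing any report code at call sites:
the user clicks, the analysis runs, and the report gains a chunk that
re-executes the same step.

The chunk is recorded even when the wrapped call later raises: a failed
attempt is part of the provenance trail. Only a serialization failure
(an argument that is neither literal-serializable nor mapped to a
placeholder) aborts *before* anything is written.
"""

from __future__ import annotations

import functools
import inspect
from typing import Callable, Mapping

from .code_serializer import Placeholder, serialize_call
from .errors import SerializationError, StateError, ValidationError
from .markdown_emitter import ChunkOptions
from .report_model import ReportDocument

__all__ = ["TracedCallable", "make_traced"]


class TracedCallable:
    """A callable that records each of its invocations in a report."""

    def __init__(
        self,
        target: Callable,
        doc: ReportDocument,
        title: str | None = None,
        title_level: int = 2,
        comment: str | None = None,
        placeholder_names: Mapping[str, str] | None = None,
        chunk_options: ChunkOptions | None = None,
        assign_to: str | None = None,
    ):
        functools.update_wrapper(self, target)
        self.target = target
        self.doc = doc
        self.title = title
        self.title_level = title_level
        self.comment = comment
        self.placeholder_names = dict(placeholder_names or {})
        self.chunk_options = chunk_options
        self.assign_to = assign_to
        self._signature = inspect.signature(target)
        self._name = getattr(target, "__name__", None)
        if not self._name or not self._name.isidentifier():
            raise ValidationError(
                "traced target must have an inspectable identifier name"
            )

    def serialize_invocation(self, *args, **kwargs) -> str:
        """Code text for one invocation, without touching the report."""
        bound = self._signature.bind(*args, **kwargs)
        arguments: dict[str, object] = {}
        for name, value in bound.arguments.items():
            parameter = self._signature.parameters[name]
            if parameter.kind in (
                inspect.Parameter.VAR_POSITIONAL,
                inspect.Parameter.VAR_KEYWORD,
            ):
                raise SerializationError(
                    f"cannot trace call with *args/**kwargs argument {name!r}; "
                    "wrap a fixed-signature function instead"
                )
            if name in self.placeholder_names:
                arguments[name] = Placeholder(self.placeholder_names[name])
            else:
                arguments[name] = value
        return serialize_call(
            self._name, arguments, assign_to=self.assign_to, dialect=self.doc.dialect
        ).text

    def __call__(self, *args, **kwargs):
        if self.doc.chunk_open:
            raise StateError("cannot trace a call while a chunk is open on the report")
        code = self.serialize_invocation(*args, **kwargs)  # may raise, before any write
        self.doc.add_complete_chunk(
            code,
            options=self.chunk_options,
            title=self.title,
            level=self.title_level,
            comment=self.comment,
        )
        return self.target(*args, **kwargs)


def make_traced(
    target: Callable,
    doc: ReportDocument,
    title: str | None = None,
    level: int = 2,
    comment: str | None = None,
    placeholder_names: Mapping[str, str] | None = None,
    chunk_options: ChunkOptions | None = None,
    assign_to: str | None = None,
) -> TracedCallable:
    """Wrap ``target`` so every call appends one re-executable chunk to
    ``doc`` before delegating.

    ``placeholder_names`` maps argument names to the variable names they
    should be referenced by in the emitted code; use it for any argument
    whose value is too large (or not serializable) to inline. With
    ``assign_to`` the emitted statement binds the call's result, so
    later chunks can refer to it.
    """
    if doc.chunk_open:
        raise StateError("report has an open chunk; close it before attaching a tracer")
    return TracedCallable(
        target,
        doc,
        title=title,
        title_level=level,
        comment=comment,
        placeholder_names=placeholder_names,
        chunk_options=chunk_options,
        assign_to=assign_to,
    )
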