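"""Named plugin registry for script-modality Logics.

Two plugin shapes are used:

* import plugins — called with no arguments, yield ObservationFacts;
* per-row transform plugins (the import ``algorithm`` hook) — called with
  one source row as a dict, return 0..n ObservationFacts;
* derived-concept plugins — called as ``plugin(patient_id, chart)`` where
  ``chart`` is the patient's chronologically sorted fact list, return
  0..n derived ObservationFacts bearing the definition's output code.

All are plain callables registered under a name; the registry keeps the
engine decoupled from where the code lives.
"""

from __future__ import annotations

from typing import Callable

from .errors import NotFoundError


class PluginRegistry:
    def __init__(self):
        self._plugins: dict[str, Callable] = {}

    def register(self, name: str, func: Callable | None = None):
        """Register a callable; usable as a decorator."""
        if func is None:
            def decorator(f: Callable) -> Callable:
                self._plugins[name] = f
                return f

            return decorator
        self._plugins[name] = func
        return func

    def get(self, name: str) -> Callable:
        try:
            return self._plugins[name]
        except KeyError:
            raise NotFoundError(f"no plugin registered under {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._plugins
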