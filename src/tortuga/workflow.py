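"""Window-navigation state machine of the entry software.

The software walks the user through login (window 1), beach details (2),
weather (3), a record-type menu (4), one of five record branches (4.x.y)
and a save window (5).  Saving is mandatory before starting another
record; after saving, "continue collecting" returns to the menu.  A crawl
that turns out to end in a nest can chain straight into the nest branch.

The machine is deliberately the *strict* variant: no record branch is
reachable without passing the beach and weather windows, and no second
record can be selected with an unsaved one pending.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "RECORD_KINDS",
    "BRANCHES",
    "WorkflowState",
    "IllegalTransitionError",
    "START",
    "transition",
    "allowed_actions",
    "all_states",
]

#: Selectable record kinds (the five-button menu; the post-hatch button
#: shares the same selection semantics).
RECORD_KINDS = ("TURTLE", "NEST_PRE", "NEST_MOVED", "NEST_POST", "CRAWL")

#: Window sequence of each record branch.
BRANCHES = {
    "TURTLE": ("4.1.1", "4.1.2", "4.1.3", "4.1.4", "4.1.5"),
    "NEST_PRE": ("4.2.1", "4.2.2", "4.2.3", "4.2.4", "4.2.5", "4.2.6",
                 "4.2.7", "4.2.8"),
    "NEST_MOVED": ("4.3.1", "4.3.2"),
    "NEST_POST": ("4.4.1", "4.4.2", "4.4.3"),
    "CRAWL": ("4.5.1",),
}

_BRANCH_OF = {w: kind for kind, ws in BRANCHES.items() for w in ws}


class IllegalTransitionError(ValueError):
    def __init__(self, state: "WorkflowState", action):
        self.state = state
        self.action = action
        super().__init__(
            f"action {action!r} is not allowed in window "
            f"{state.current_window} (saved={state.saved}, "
            f"pending={state.pending_record_kind})"
        )


@dataclass(frozen=True)
class WorkflowState:
    current_window: str
    saved: bool = False
    pending_record_kind: str = "none"

    def __post_init__(self) -> None:
        at_menu_side = (self.current_window in ("1", "2", "3", "4")
                        or (self.current_window == "5" and self.saved))
        if (self.pending_record_kind == "none") != at_menu_side:
            raise ValueError(
                f"invalid state: window {self.current_window}, "
                f"saved={self.saved}, pending={self.pending_record_kind}"
            )
        if self.pending_record_kind not in ("none",) + RECORD_KINDS:
            raise ValueError(
                f"unknown record kind {self.pending_record_kind!r}"
            )


#: Initial state: the login window.
START = WorkflowState("1")


def _actions(state: WorkflowState) -> dict:
    """Map of applicable action -> successor state."""
    w, saved, kind = (state.current_window, state.saved,
                      state.pending_record_kind)
    out: dict = {}
    if w == "1":
        out[("login_ok",)] = WorkflowState("2")
    elif w == "2":
        out[("next",)] = WorkflowState("3")
    elif w == "3":
        out[("next",)] = WorkflowState("4")
        out[("back",)] = WorkflowState("2")
    elif w == "4":
        out[("back",)] = WorkflowState("3")
        for k in RECORD_KINDS:
            out[("select", k)] = WorkflowState(BRANCHES[k][0],
                                               pending_record_kind=k)
    elif w == "5":
        if saved:
            out[("continue_collecting",)] = WorkflowState("4")
        else:
            out[("save",)] = WorkflowState("5", saved=True)
            out[("back",)] = WorkflowState(BRANCHES[kind][-1],
                                           pending_record_kind=kind)
    else:  # a branch window
        seq = BRANCHES[kind]
        i = seq.index(w)
        nxt = seq[i + 1] if i + 1 < len(seq) else "5"
        out[("next",)] = (WorkflowState(nxt, pending_record_kind=kind)
                          if nxt != "5"
                          else WorkflowState("5", pending_record_kind=kind))
        if i == 0:
            # backing out of the first branch window abandons the selection
            out[("back",)] = WorkflowState("4")
        else:
            out[("back",)] = WorkflowState(seq[i - 1],
                                           pending_record_kind=kind)
        if w == "4.5.1":
            # a crawl that found a nest chains into the nest branch
            out[("chain_to_nest",)] = WorkflowState(
                BRANCHES["NEST_PRE"][0], pending_record_kind="NEST_PRE")
    return out


def transition(state: WorkflowState, action) -> WorkflowState:
    """Apply *action* (a tuple like ``("next",)`` or ``("select", kind)``);
    raises :class:`IllegalTransitionError` when not applicable."""
    if isinstance(action, str):
        action = (action,)
    succ = _actions(state)
    if action not in succ:
        raise IllegalTransitionError(state, action)
    return succ[action]


def allowed_actions(state: WorkflowState) -> set:
    """Exactly the actions for which :func:`transition` does not raise."""
    return set(_actions(state))


def all_states() -> list[WorkflowState]:
    """Every reachable state (breadth-first from :data:`START`)."""
    seen = [START]
    frontier = [START]
    while frontier:
        state = frontier.pop()
        for nxt in _actions(state).values():
            if nxt not in seen:
                seen.append(nxt)
                frontier.append(nxt)
    return seen
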