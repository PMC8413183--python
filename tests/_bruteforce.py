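"""Independent truth-table evaluator used as an oracle for the rule engine.

Works directly on the raw JSON DSL documents (dicts) and on plain field
assignments, with hand-written Kleene truth tables, so it shares no code
path with uveaclass.criteria_engine.

Field assignment (env) keys follow criteria_engine.referenced_fields:
("finding", code) -> "present" | "absent" | "unknown" | ("present", grade)
("test", code)    -> "positive" | "negative" | "unknown"
("course",)       -> course value;  ("laterality",) -> laterality value
Missing keys mean unknown.
"""

NOT = {"T": "F", "F": "T", "U": "U"}


def _and2(a, b):
    if a == "F" or b == "F":
        return "F"
    if a == "U" or b == "U":
        return "U"
    return "T"


def _or2(a, b):
    if a == "T" or b == "T":
        return "T"
    if a == "U" or b == "U":
        return "U"
    return "F"


def _plain(state):
    return "present" if isinstance(state, tuple) else state


def _grade(state):
    if state == "absent":
        return 0
    if isinstance(state, tuple):
        return state[1]
    return None


def bf_eval(node: dict, env: dict) -> str:
    """Evaluate a raw DSL expression document to 'T' | 'F' | 'U'."""
    if "and" in node:
        out = "T"
        for child in node["and"]:
            out = _and2(out, bf_eval(child, env))
        return out
    if "or" in node:
        out = "F"
        for child in node["or"]:
            out = _or2(out, bf_eval(child, env))
        return out
    if "not" in node:
        return NOT[bf_eval(node["not"], env)]
    if "finding" in node:
        state = _plain(env.get(("finding", node["finding"]), "unknown"))
        if state == "unknown":
            return "U"
        return "T" if state == node["is"] else "F"
    if "test" in node:
        state = env.get(("test", node["test"]), "unknown")
        if state == "unknown":
            return "U"
        return "T" if state == node["is"] else "F"
    if "course_in" in node:
        value = env.get(("course",), "unknown")
        if value == "unknown" and not node.get("closed", False):
            return "U"
        return "T" if value in node["course_in"] else "F"
    if "laterality_in" in node:
        value = env.get(("laterality",), "unknown")
        if value == "unknown" and not node.get("closed", False):
            return "U"
        return "T" if value in node["laterality_in"] else "F"
    if "grade_lt" in node:
        lo = _grade(env.get(("finding", node["grade_lt"][0]), "unknown"))
        hi = _grade(env.get(("finding", node["grade_lt"][1]), "unknown"))
        if lo is None or hi is None:
            return "U"
        return "T" if lo < hi else "F"
    if "grade_ge" in node:
        g = _grade(env.get(("finding", node["grade_ge"][0]), "unknown"))
        return "T" if (g or 0) >= node["grade_ge"][1] else "F"
    if "finding_in" in node:
        state = _plain(env.get(("finding", node["finding_in"][0]), "unknown"))
        return "T" if state in node["finding_in"][1] else "F"
    if "test_in" in node:
        state = env.get(("test", node["test_in"][0]), "unknown")
        return "T" if state in node["test_in"][1] else "F"
    if "const" in node:
        return "T" if node["const"] else "F"
    raise ValueError(f"unrecognized node: {sorted(node)}")


def bf_verdict(ruleset_doc: dict, env: dict) -> str:
    """Verdict per the documented semantics, from the raw rule set document."""
    for excl in ruleset_doc.get("exclusions", []):
        if bf_eval(excl, env) == "T":
            return "excluded"
    crit = bf_eval(ruleset_doc["criteria"], env)
    if crit == "T":
        return "classified"
    if crit == "U":
        return "indeterminate"
    return "criteria_not_met"
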