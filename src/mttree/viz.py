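"""Tree rendering: indented text layout and DOT (Graphviz) export.

Both renderers are pure functions of the model. Summaries are printed to 3
significant digits with a fixed per-type format (mean / modal level with its
proportion / rate) so snapshot tests stay stable.
"""

from __future__ import annotations

from .datamodel import TargetType
from .tree import TreeModel, TreeNode


def _fmt(x) -> str:
    return f"{float(x):.3g}"


def _summary_str(model: TreeModel, node: TreeNode) -> str:
    parts = []
    for spec, summ in zip(model.targets, node.summaries):
        if spec.ttype is TargetType.CONTINUOUS:
            parts.append(f"{spec.name}={_fmt(summ['mean'])}")
        elif spec.ttype is TargetType.CATEGORICAL:
            prop = summ["proportions"].get(summ["mode"], 0.0)
            parts.append(f"{spec.name}={summ['mode']}({_fmt(prop)})")
        else:
            parts.append(f"{spec.name}={_fmt(summ['rate'])}/u")
    return " ".join(parts)


def _rule_str(node: TreeNode, side: str) -> str:
    cand = node.split
    if cand.kind == "numeric_threshold":
        op = "<=" if side == "left" else ">"
        return f"{cand.feature} {op} {_fmt(cand.threshold)}"
    op = "=" if side == "left" else "!="
    return f"{cand.feature} {op} {cand.threshold}"


def render_text(model: TreeModel, max_width: int = 120) -> str:
    """One line per node, indented by depth: rule, n, per-target summaries."""
    lines: list[str] = []

    def walk(node: TreeNode, label: str):
        pad = "  " * node.depth
        line = f"{pad}{label} [n={node.n}] {_summary_str(model, node)}"
        lines.append(line[:max_width])
        if not node.is_leaf:
            walk(node.children[0], _rule_str(node, "left"))
            walk(node.children[1], _rule_str(node, "right"))

    walk(model.root, "root")
    return "\n".join(lines) + "\n"


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def render_dot(model: TreeModel) -> str:
    """DOT digraph: one box per node, edges labeled with the split outcome."""
    lines = ["digraph tree {", '  node [shape=box, fontname="Helvetica"];']
    for node in model.nodes():
        label = f"node {node.node_id}\\nn={node.n}\\n{_dot_escape(_summary_str(model, node))}"
        if not node.is_leaf:
            label = f"{_dot_escape(node.split.feature)}\\n{label}"
        lines.append(f'  n{node.node_id} [label="{label}"];')
    for node in model.nodes():
        if node.is_leaf:
            continue
        for side, child in zip(("left", "right"), node.children):
            edge_label = _dot_escape(_rule_str(node, side).split(" ", 1)[1])
            lines.append(
                f'  n{node.node_id} -> n{child.node_id} [label="{edge_label}"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"
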