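"""Loop decomposition: dot-bracket structures to structure arrays.

Pseudoknot-free dot-brackets are converted into per-nucleotide structural
codes: paired positions become ``L``/``R`` (left/right side of a stem) and
each maximal unpaired run is classified by the loop that contains it —
hairpin ``H``, bulge ``B``, internal loop ``I``, multiloop ``M``, external
loop ``X``, or end ``E`` when the run touches a terminus and is enclosed
by no pair.
"""

from __future__ import annotations

from .structure_io import DotBracket, StructureArray

__all__ = ["pair_table", "annotate", "annotate_all"]


def pair_table(dbn: DotBracket) -> dict[int, int]:
    """Match brackets into a 1-based pairing map.

    Returns a dict mapping every position ``1..L`` to its partner, or to 0
    if unpaired. ``(`` at i matched to ``)`` at j gives partner[i]=j and
    partner[j]=i (an involution with properly nested pairs).
    """
    partner = {i: 0 for i in range(1, len(dbn.brackets) + 1)}
    stack: list[int] = []
    for i, ch in enumerate(dbn.brackets, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(
                    f"record {dbn.name!r}: unbalanced ')' at position {i}"
                )
            j = stack.pop()
            partner[j] = i
            partner[i] = j
    if stack:
        raise ValueError(
            f"record {dbn.name!r}: unbalanced '(' at position {stack[-1]}"
        )
    return partner


def annotate(dbn: DotBracket) -> StructureArray:
    """Annotate a pseudoknot-free dot-bracket as a structure array.

    Every ``(`` becomes ``L`` and every ``)`` becomes ``R``. Unpaired runs
    are classified by their nearest enclosing pair: no enclosing pair gives
    ``E`` at the termini and ``X`` strictly between exterior helices; an
    enclosing loop with zero branch helices gives ``H``; one branch helix
    gives ``B`` (unpaired on one side only) or ``I`` (both sides); two or
    more branches give ``M``. Lone pairs count as helices; no minimum
    hairpin size is imposed.
    """
    partner = pair_table(dbn)
    L = len(dbn.brackets)
    codes = [""] * (L + 1)  # 1-based

    # enclosing[i] = opening position of the innermost pair containing i,
    # or 0 for exterior positions.
    enclosing = [0] * (L + 2)
    stack: list[int] = []
    for i, ch in enumerate(dbn.brackets, start=1):
        if ch == "(":
            enclosing[i] = stack[-1] if stack else 0
            stack.append(i)
            codes[i] = "L"
        elif ch == ")":
            stack.pop()
            enclosing[i] = stack[-1] if stack else 0
            codes[i] = "R"
        else:
            enclosing[i] = stack[-1] if stack else 0

    # children[p] = opening positions of pairs directly inside pair (p, partner[p]);
    # children[0] = exterior (top-level) helices.
    children: dict[int, list[int]] = {0: []}
    for i in range(1, L + 1):
        if partner[i] > i:  # an opening bracket
            children.setdefault(i, [])
            children[enclosing[i]].append(i)

    def classify_loop(p: int) -> str:
        """Structure code for unpaired runs inside the loop opened at p."""
        branches = children.get(p, [])
        if len(branches) == 0:
            return "H"
        if len(branches) >= 2:
            return "M"
        c = branches[0]
        d = partner[c]
        q = partner[p]
        left = c - p - 1  # unpaired between ( of loop and ( of branch
        right = q - d - 1  # unpaired between ) of branch and ) of loop
        if left > 0 and right > 0:
            return "I"
        return "B"

    loop_code: dict[int, str] = {p: classify_loop(p) for p in children if p != 0}

    i = 1
    while i <= L:
        if codes[i]:
            i += 1
            continue
        j = i
        while j <= L and not codes[j]:
            j += 1
        # unpaired run i..j-1
        p = enclosing[i]
        if p == 0:
            code = "E" if (i == 1 or j - 1 == L) else "X"
        else:
            code = loop_code[p]
        for t in range(i, j):
            codes[t] = code
        i = j

    return StructureArray(name=dbn.name, codes="".join(codes[1:]))


def annotate_all(dbns) -> list[StructureArray]:
    """Annotate an iterable of dot-brackets, preserving order."""
    return [annotate(d) for d in dbns]
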