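"""Brute-force 5'-origin enumerator.

Independent oracle for read classification: it knows nothing about seed
anchoring or G-run stripping.  For a read it simply tries *every* origin
(start coordinate on the construct, number of leading artifact Gs) and keeps
the ones fully consistent with the template -- all read bases aligned to
known template positions must match, cassette positions are free, artifact
bases must be G.  A read is ambiguous when two consistent origins differ in
start position or implied 7-mer; a +1..+7 G first base is excluded as
unreliable even when the origin is unique.
"""

from __future__ import annotations

from startmer.construct import ConstructTemplate


def enumerate_origins(
    read: str, template: ConstructTemplate, max_artifact_g: int = 2
) -> list[tuple[int, int]]:
    """All (start, n_artifact_g) origins consistent with the read."""
    known = (
        template.promoter_seq
        + "?" * template.cassette_len
        + template.downstream_seq
    )
    length = len(known)
    origins = []
    for g in range(max_artifact_g + 1):
        if len(read) <= g or any(b != "G" for b in read[:g]):
            continue
        for start in range(length):
            ok = True
            for i in range(g, len(read)):
                coord = start + i - g
                if coord >= length:
                    ok = False
                    break
                t = known[coord]
                if t != "?" and t != read[i]:
                    ok = False
                    break
            if ok:
                origins.append((start, g))
    return origins


def brute_force_classify(
    read: str, template: ConstructTemplate, max_artifact_g: int = 2
) -> tuple[str, int | None, int | None, str | None]:
    """Category tuple ``(category, start, n_artifact_g, sevenmer)`` from
    exhaustive origin enumeration (same output convention as the package
    classifier, derived by an entirely different route)."""
    tss = template.expected_tss_index
    clen = template.cassette_len
    origins = enumerate_origins(read, template, max_artifact_g)
    interps: list[tuple[int, int, str | None]] = []
    seen: set[tuple[int, str | None]] = set()
    for start, g in origins:
        sevenmer = None
        if start == tss and read[g] != "G":
            sevenmer = read[g : g + clen]
        key = (start, sevenmer)
        if key not in seen:
            seen.add(key)
            interps.append((g, start, sevenmer))
    if not interps:
        return ("no_seed", None, None, None)
    if len(interps) > 1:
        return ("ambiguous_plus1G", None, None, None)
    g, start, sevenmer = interps[0]
    if sevenmer is not None:
        return ("cassette_start", start, g, sevenmer)
    if tss <= start < tss + clen:
        if read[g] == "G":
            return ("ambiguous_plus1G", None, None, None)
        return ("downstream_start", start, g, None)
    if start < tss:
        return ("upstream_start", start, g, None)
    return ("downstream_start", start, g, None)
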