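"""Independent brute-force oracles for the segregation models.

The compound-het oracle enumerates top-down: founder two-site phases and
per-child transmission choices generate genotypes that are compared to the
observed ones, the reverse direction of the package's bottom-up haplotype
filtering. Trans is accepted only when assignments exist and every one
places the pair on different parental haplotypes in each affected member.
"""

from __future__ import annotations

from mendelsieve import Affection, Pedigree, Zygosity

ALT_COUNT = {
    Zygosity.HOM_REF: 0,
    Zygosity.HET: 1,
    Zygosity.HOM_ALT: 2,
}

CARRIER = (Zygosity.HET, Zygosity.HOM_ALT)


def oracle_ar_hom(ped: Pedigree, zyg: dict[str, Zygosity]) -> bool:
    for m in ped.members:
        z = zyg[m.individual_id]
        if m.affected is Affection.AFFECTED and z is not Zygosity.HOM_ALT:
            return False
        if m.affected is Affection.UNAFFECTED and z is Zygosity.HOM_ALT:
            return False
    for m in ped.members:
        if m.affected is not Affection.AFFECTED:
            continue
        for pid in (m.father_id, m.mother_id):
            if pid is not None and pid in ped and zyg[pid] is not Zygosity.HET:
                return False
    return True


def oracle_dominant(
    ped: Pedigree, zyg: dict[str, Zygosity], mode: str
) -> bool:
    for m in ped.members:
        z = zyg[m.individual_id]
        carrier = z in CARRIER
        if m.affected is Affection.AFFECTED and not carrier:
            return False
        if (
            m.affected is Affection.UNAFFECTED
            and carrier
            and mode == "strict"
        ):
            return False
    return True


_HAPS = ((0, 0), (1, 0), (0, 1), (1, 1))  # (has variant a, has variant b)


def oracle_comp_het(
    ped: Pedigree, za: dict[str, Zygosity], zb: dict[str, Zygosity]
) -> bool:
    """Strict-config verdict by exhaustive phase/transmission enumeration."""
    parent_ids = {
        pid
        for m in ped.members
        if m.affected is Affection.AFFECTED
        for pid in (m.father_id, m.mother_id)
        if pid is not None
    }
    for m in ped.members:
        if m.affected is Affection.AFFECTED:
            if za[m.individual_id] is not Zygosity.HET:
                return False
            if zb[m.individual_id] is not Zygosity.HET:
                return False
        elif m.affected is Affection.UNAFFECTED:
            # double carriage in a parent of an affected member is a phase
            # question, not an automatic veto
            if (
                za[m.individual_id] in CARRIER
                and zb[m.individual_id] in CARRIER
                and m.individual_id not in parent_ids
            ):
                return False

    ordered = []
    placed: set[str] = set()
    pending = list(ped.members)
    while pending:
        for m in list(pending):
            deps = [p for p in (m.father_id, m.mother_id) if p in ped]
            if all(d in placed for d in deps):
                ordered.append(m)
                placed.add(m.individual_id)
                pending.remove(m)
                break
        else:
            raise AssertionError("pedigree not acyclic")

    affected_ids = {
        m.individual_id for m in ped.members if m.affected is Affection.AFFECTED
    }
    found = {"trans": False, "nontrans": False}

    def matches(iid: str, h1, h2) -> bool:
        return (
            h1[0] + h2[0] == ALT_COUNT[za[iid]]
            and h1[1] + h2[1] == ALT_COUNT[zb[iid]]
        )

    def is_trans(haps) -> bool:
        for iid in affected_ids:
            h1, h2 = haps[iid]
            if (h1[0] and h1[1]) or (h2[0] and h2[1]):
                return False
        return True

    def walk(idx: int, haps) -> None:
        if found["trans"] and found["nontrans"]:
            return
        if idx == len(ordered):
            found["trans" if is_trans(haps) else "nontrans"] = True
            return
        m = ordered[idx]
        iid = m.individual_id
        paternal = (
            list(haps[m.father_id]) if m.father_id in ped else list(_HAPS)
        )
        maternal = (
            list(haps[m.mother_id]) if m.mother_id in ped else list(_HAPS)
        )
        for h1 in paternal:
            for h2 in maternal:
                if matches(iid, h1, h2):
                    haps[iid] = (h1, h2)
                    walk(idx + 1, haps)
                    del haps[iid]

    walk(0, {})
    return found["trans"] and not found["nontrans"]


def mendelian_consistent(
    ped: Pedigree, genotypes: dict[str, tuple[int, int]]
) -> bool:
    """No child allele absent from its genotyped parents (single locus)."""
    for m in ped.members:
        child = genotypes[m.individual_id]
        father = genotypes.get(m.father_id) if m.father_id in ped else None
        mother = genotypes.get(m.mother_id) if m.mother_id in ped else None
        ok = False
        for x, y in ((child[0], child[1]), (child[1], child[0])):
            from_f = father is None or x in father
            from_m = mother is None or y in mother
            if from_f and from_m:
                ok = True
                break
        if not ok:
            return False
    return True
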