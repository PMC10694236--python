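"""Tiny hand-written flux networks shared across test modules."""

from sulfurgem.core import MetabolicModel, Metabolite, Reaction, add_boundary


def chain_model(uptake=5.0):
    """EX_a (uptake <= 5) -> a -> b -> demand: optimum forced to the uptake."""
    m = MetabolicModel("chain")
    m.add_metabolite(Metabolite("a_e", compartment="e"))
    m.add_metabolite(Metabolite("a_c", compartment="c"))
    m.add_metabolite(Metabolite("b_c", compartment="c"))
    add_boundary(m, "a_e", "exchange")
    m.reactions["EX_a_e"].lower_bound = -uptake
    m.add_reaction(Reaction("T", {"a_e": -1, "a_c": 1}, lower_bound=0))
    m.add_reaction(Reaction("AB", {"a_c": -1, "b_c": 1}, lower_bound=0))
    add_boundary(m, "b_c", "demand")
    return m


def diamond_model():
    """Two equal-yield routes of length 1 and 2; pFBA must take the short one."""
    m = chain_model()
    m.add_metabolite(Metabolite("c_c", compartment="c"))
    m.add_reaction(Reaction("AC", {"a_c": -1, "c_c": 1}, lower_bound=0))
    m.add_reaction(Reaction("CB", {"c_c": -1, "b_c": 1}, lower_bound=0))
    return m


def parallel_paths_model():
    """Three routes of lengths 1, 2 and 3 between substrate and product."""
    m = diamond_model()
    m.add_metabolite(Metabolite("d_c", compartment="c"))
    m.add_metabolite(Metabolite("e_c", compartment="c"))
    m.add_reaction(Reaction("AD", {"a_c": -1, "d_c": 1}, lower_bound=0))
    m.add_reaction(Reaction("DE", {"d_c": -1, "e_c": 1}, lower_bound=0))
    m.add_reaction(Reaction("EB", {"e_c": -1, "b_c": 1}, lower_bound=0))
    return m
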