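"""Built-in English stopword list, version 1.

A compact list of function words common in scientific prose.  Kept small on
purpose: aggressive stopping risks deleting informative short terms from
figure legends.
"""

STOPWORDS_VERSION = 1

STOPWORDS = frozenset("""
a about above after again against all also am an and any are as at be because
been before being below between both but by can cannot could did do does doing
down during each few for from further had has have having he her here hers him
his how i if in into is it its itself just me more most my no nor not of off on
once only or other our ours out over own s same she should so some such t than
that the their theirs them then there these they this those through to too
under until up very was we were what when where which while who whom why will
with would you your yours
""".split())
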