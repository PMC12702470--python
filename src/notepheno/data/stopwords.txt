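# Default stop-word list: high-frequency function words removed from the
# search token stream. Cue matching runs on the unfiltered stream, so this
# list cannot break cue phrases; even so, the load-bearing cue words
# (of, with, for, no, not, have, may ...) are deliberately absent.
# One word per line; '#' comments.
the
a
an
and
or
but
is
are
was
were
be
been
being
am
to
in
on
at
by
it
this
that
these
those
there
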