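i
me
my
mine
myself
we
us
our
ours
ourselves
you
your
yours
yourself
yourselves
he
him
his
himself
she
her
hers
herself
it
its
itself
they
them
their
theirs
themselves
who
whom
whose
which
what
this
that
these
those
anyone
everyone
someone
no one
anybody
everybody
somebody
nobody
anything
everything
something
nothing
one
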