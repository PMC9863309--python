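# Minimal English function-word stop list.
# Deliberately small: generic content words ("study", "human") are kept so
# that cluster themes reflect actual corpus usage.
a
an
the
and
or
nor
but
if
then
else
when
while
where
why
how
of
in
on
for
with
to
from
by
at
as
into
onto
about
above
below
over
under
between
during
before
after
through
against
within
without
again
further
once
is
are
was
were
be
been
being
am
do
does
did
done
has
have
had
having
can
could
may
might
will
would
shall
should
must
this
that
these
those
it
its
itself
they
them
their
theirs
we
us
our
ours
you
your
yours
he
him
his
she
her
hers
i
me
my
mine
who
whom
whose
which
what
not
no
yes
so
such
than
too
very
both
each
few
more
most
other
some
any
all
own
same
here
there
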